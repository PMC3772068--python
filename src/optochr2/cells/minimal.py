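"""Minimal passive host cell for fast tests and threshold sanity checks.

A single-variable membrane carrying an instantaneous inward rectifier
(same functional form as the atrial model's IK1) and an ohmic leak.
It is not excitable — there is no sodium current — but it depolarizes
above the -20 mV optical-threshold criterion under sufficient light,
which is all the strength-duration machinery needs.
"""

from __future__ import annotations

import math

import numpy as np

from .chr2core import chr2_current_nb, chr2_derivs_nb


class MinimalHost:
    name = "minimal"
    n_cell_states = 1
    n_states = 5
    state_names = ("V", "o1", "o2", "c2", "p")
    v_index = 0

    def __init__(self, gk1: float = 0.1, ek: float = -90.0,
                 gleak: float = 0.02, eleak: float = -70.0):
        self.gk1 = gk1
        self.ek = ek
        self.gleak = gleak
        self.eleak = eleak
        self.y0 = np.array([self._rest(), 0.0, 0.0, 0.0, 0.0])

    def ik1(self, v: float) -> float:
        return self.gk1 * (v - self.ek) / (1.0 + math.exp(0.07 * (v + 80.0)))

    def _rest(self) -> float:
        from scipy.optimize import brentq
        f = lambda v: self.ik1(v) + self.gleak * (v - self.eleak)
        return brentq(f, self.ek, self.eleak + 1e-9)

    def rhs(self, t, y, irr, pv):
        v = y[0]
        ichr2 = chr2_current_nb(y[1], y[2], v, pv)
        dy = np.empty(5)
        dy[0] = -(self.ik1(v) + self.gleak * (v - self.eleak) + ichr2)
        dy[1], dy[2], dy[3], dy[4] = chr2_derivs_nb(y[1], y[2], y[3], y[4],
                                                    v, irr, pv)
        return dy

    def currents(self, y, pv) -> dict:
        return {"IK1": self.ik1(y[0]),
                "IChR2": chr2_current_nb(y[1], y[2], y[0], pv)}

    def without_ik1(self) -> "MinimalHost":
        """Copy with the rectifier removed; the membrane rests at the leak
        reversal, depolarized relative to the intact cell — losing IK1 both
        removes opposing current and moves rest closer to threshold."""
        return MinimalHost(gk1=0.0, ek=self.ek, gleak=self.gleak,
                           eleak=self.eleak)
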