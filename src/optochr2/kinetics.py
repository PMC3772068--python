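"""Four-state Markov model of the ChR2(H134R) photocurrent.

The photocycle has two closed states (C1, dark-adapted; C2, light-adapted)
and two open states (O1, high conductance; O2, low conductance) connected
by seven transition rates, two of which (k1, k2) are light-driven::

          k1            e12
    C1 <------> O1 <----------> O2
          Gd1        e21          |  Gd2
     ^                            v
     +----------- Gr ----------- C2

C1 is eliminated by the conservation law C1 = 1 - O1 - O2 - C2, so the
integrated state vector is (O1, O2, C2, p) where p is the retinal
activation variable with sigmoidal steady state S0(theta) and time
constant tau_ChR2.

The membrane current is I = g * G(V)*(V - E) * (O1 + gamma*O2) with an
empirical inward-rectification function G(V).  G(V) alone has a 1/V pole;
the product G(V)*(V - E) with E = 0 is the smooth closed form
``rect_a - rect_b*exp(-V/rect_vs)``, which is what this module evaluates,
so the current is defined and smooth at V = 0.  A consequence of the
printed coefficients is that the current's actual zero crossing sits near
+13.6 mV rather than at the nominal 0 mV reversal potential; the
formulation is kept as published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ChR2Params

__all__ = [
    "ChR2State",
    "photon_flux",
    "s0",
    "light_rates",
    "voltage_rates",
    "rectification_driving",
    "chr2_current",
    "derivatives",
    "dark_steady_state",
]

_SIMPLEX_TOL = 1e-6


@dataclass
class ChR2State:
    """Occupancies of the photocycle (C1 implied by conservation)."""

    o1: float = 0.0
    o2: float = 0.0
    c2: float = 0.0
    p: float = 0.0

    @property
    def c1(self) -> float:
        return 1.0 - self.o1 - self.o2 - self.c2

    def as_array(self) -> np.ndarray:
        return np.array([self.o1, self.o2, self.c2, self.p], float)

    @classmethod
    def from_array(cls, y) -> "ChR2State":
        return cls(o1=float(y[0]), o2=float(y[1]), c2=float(y[2]), p=float(y[3]))

    def validate(self, tol: float = _SIMPLEX_TOL) -> None:
        vals = (self.o1, self.o2, self.c2, self.p, self.c1)
        if any(not -tol <= v <= 1 + tol for v in vals):
            raise ValueError(f"state outside the probability simplex: {self}")


def photon_flux(irradiance: float, params: ChR2Params) -> float:
    """Photon absorption rate F in ms^-1 for a given irradiance.

    F = 0.0006 * I * lambda / w_loss, i.e. sigma_ret*I*lambda/(h*c*w_loss)
    with the unit conversions folded into the 0.0006 coefficient
    (ms^-1 per mW/mm^2 per nm).  Linear in irradiance.
    """
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    return params.flux_coeff * irradiance * params.lambda_max / params.w_loss


def s0(theta: float) -> float:
    """Steady-state retinal activation, 0.5*(1 + tanh(120*(theta - 0.1)))."""
    return 0.5 * (1.0 + math.tanh(120.0 * (theta - 0.1)))


def light_rates(irradiance: float, p: float, params: ChR2Params) -> dict:
    """Light-dependent rates {k1, k2, e12, e21} in ms^-1.

    k1 = eps1*F*p and k2 = eps2*F*p gate the closed->open transitions
    through the activation variable p; the inter-open rates grow
    logarithmically with irradiance, e = e_dark + c1*ln(1 + I/c2).
    """
    F = photon_flux(irradiance, params)
    log_term = math.log1p(irradiance / params.log_c2)
    return {
        "k1": params.k1_scale * params.eps1 * F * p,
        "k2": params.k2_scale * params.eps2 * F * p,
        "e12": params.e12_dark + params.log_c1_12 * log_term,
        "e21": params.e21_dark + params.log_c1_21 * log_term,
    }


def voltage_rates(v: float, params: ChR2Params) -> dict:
    """Voltage-dependent rates {gd1, gd2, gr} in ms^-1.

    Gd1(V) = 0.075 + 0.043*tanh((V+20)/-20) slows the O1 closure at
    depolarized potentials; Gr(V) = gr_pref*exp(-0.02115*V) makes the
    dark recovery C2 -> C1 slower at more positive voltages.
    """
    gd1 = params.gd1_base + params.gd1_amp * math.tanh((v + params.gd1_v0) / params.gd1_vs)
    gr = params.gr_pref * math.exp(-params.gr_slope * v)
    return {"gd1": gd1, "gd2": params.gd2, "gr": gr}


def rectification_driving(v: float, params: ChR2Params) -> float:
    """The smooth product G(V)*(V - E_rev) in mV (dimensionless G).

    With the default e_rev = 0 this is the closed-form numerator
    rect_a - rect_b*exp(-V/rect_vs), finite and continuous at V = 0.
    """
    num = params.rect_a - params.rect_b * np.exp(-np.asarray(v, float) / params.rect_vs)
    if params.e_rev == 0.0:
        return num if num.ndim else float(num)
    # G(V) itself has a 1/V pole that only cancels for e_rev = 0
    out = num * (np.asarray(v, float) - params.e_rev) / np.asarray(v, float)
    return out if out.ndim else float(out)


def chr2_current(state: ChR2State, v, params: ChR2Params):
    """ChR2 current density in pA/pF (uA/uF): g*G(V)(V-E)*(O1 + gamma*O2)."""
    state.validate()
    return params.g_chr2 * rectification_driving(v, params) * (
        state.o1 + params.gamma * state.o2
    )


def derivatives_raw(y, v: float, irradiance: float, params: ChR2Params) -> np.ndarray:
    """Time derivative of (o1, o2, c2, p); no validation (hot path)."""
    o1, o2, c2, p = y
    c1 = 1.0 - o1 - o2 - c2
    F = params.flux_coeff * irradiance * params.lambda_max / params.w_loss
    log_term = math.log1p(irradiance / params.log_c2)
    k1 = params.k1_scale * params.eps1 * F * p
    k2 = params.k2_scale * params.eps2 * F * p
    e12 = params.e12_dark + params.log_c1_12 * log_term
    e21 = params.e21_dark + params.log_c1_21 * log_term
    gd1 = params.gd1_base + params.gd1_amp * math.tanh((v + params.gd1_v0) / params.gd1_vs)
    gr = params.gr_pref * math.exp(-params.gr_slope * v)
    do1 = k1 * c1 - (gd1 + e12) * o1 + e21 * o2
    do2 = k2 * c2 + e12 * o1 - (params.gd2 + e21) * o2
    dc2 = params.gd2 * o2 - (k2 + gr) * c2
    s_inf = 0.5 * (1.0 + math.tanh(120.0 * (params.theta_scale * irradiance - 0.1)))
    dp = (s_inf - p) / params.tau_chr2
    return np.array([do1, do2, dc2, dp])


def derivatives(state: ChR2State, v: float, irradiance: float,
                params: ChR2Params) -> np.ndarray:
    """Validated time derivative of the state vector (o1, o2, c2, p).

    dC1/dt is implied by conservation: the sum of the four occupancy
    derivatives is identically zero.
    """
    if not (math.isfinite(v) and math.isfinite(irradiance)):
        raise ValueError("v and irradiance must be finite")
    state.validate()
    return derivatives_raw(state.as_array(), v, irradiance, params)


def dark_steady_state(params: ChR2Params) -> ChR2State:
    """Dark-adapted fixed point: everything in C1, retinal inactive."""
    return ChR2State(o1=0.0, o2=0.0, c2=0.0, p=0.0)
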