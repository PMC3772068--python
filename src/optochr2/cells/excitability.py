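"""Optical excitability analyses: thresholds, strength-duration curves,
IK1 swap and sustained optical pacing."""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ..params import ChR2Params
from ..protocols import LightProtocol, SolverSettings
from .engine import equilibrate, run_cell

__all__ = ["optical_threshold", "strength_duration", "swap_ik1",
           "pace_train", "PaceTrainResult"]

#: Excitation criterion: membrane voltage must exceed this level ...
THRESHOLD_V = -20.0
#: ... within this many ms of light onset.
THRESHOLD_WINDOW = 400.0


def _v_max(cell, width, irradiance, params, solver, onset=0.0):
    light = LightProtocol.single_pulse(onset, width, irradiance,
                                       total=onset + THRESHOLD_WINDOW)
    res = run_cell(cell, light, params=params, dt_out=0.5, solver=solver)
    m = res.time >= onset
    return float(np.max(res.voltage[m]))


def optical_threshold(cell, pulse_width: float, params: ChR2Params,
                      irr_cap: float = 10.0, rel_tol: float = 1e-3,
                      solver: SolverSettings | None = None) -> float:
    """Minimum irradiance (mW/mm^2) driving V above -20 mV within 400 ms.

    Deterministic bisection on the excitation error V_max - (-20) between
    zero and ``irr_cap``.  Raises if the criterion is unreachable below
    the cap.
    """
    if pulse_width <= 0:
        raise ValueError("pulse_width must be > 0")
    solver = solver or SolverSettings()
    err = lambda irr: _v_max(cell, pulse_width, irr, params, solver) - THRESHOLD_V
    hi = irr_cap
    if err(hi) < 0:
        raise ValueError(f"no optical threshold below {irr_cap} mW/mm^2 "
                         f"for a {pulse_width} ms pulse")
    lo = 0.0
    # bracket down from the cap for a tight relative tolerance
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if err(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi


def strength_duration(cell, widths, params: ChR2Params,
                      g_scale: float = 1.0, **kwargs) -> np.ndarray:
    """Threshold irradiance per pulse width (the strength-duration curve).

    ``g_scale`` multiplies the ChR2 conductance, for expression-level
    sweeps.  Returns an array aligned with ``widths``.
    """
    widths = np.asarray(widths, float)
    if np.any(widths <= 0) or np.any(np.diff(widths) < 0):
        raise ValueError("widths must be positive and sorted")
    p = params.replace(g_chr2=params.g_chr2 * g_scale)
    return np.array([optical_threshold(cell, w, p, **kwargs) for w in widths])


def swap_ik1(cell, formulation: str, params: ChR2Params,
             equilibrate_ms: float = 60000.0,
             solver: SolverSettings | None = None, **kwargs):
    """Return a copy of ``cell`` with its IK1 replaced and re-equilibrated.

    ``formulation`` is 'native' or 'purkinje' (Sampson-type instantaneous
    rectifier).  The returned cell's resting state is the end point of a
    60 s dark integration, so the altered rectifier balance is settled
    before any optical experiment.
    """
    if hasattr(cell, "with_ik1"):
        new = cell.with_ik1(formulation, **kwargs)
    elif formulation == "native":
        new = copy.deepcopy(cell)
    else:
        raise ValueError(f"{cell.name} has no alternative IK1 formulation")
    equilibrate(new, params, duration=equilibrate_ms, solver=solver)
    return new


@dataclass
class PaceTrainResult:
    beat_times: np.ndarray        # ms, light onset of each beat
    peak_i_chr2: np.ndarray       # pA/pF, per-beat peak magnitude
    occupancy_max: dict           # state -> per-beat max occupancy
    occupancy_min: dict           # state -> per-beat min occupancy
    complete: bool = True
    message: str = ""

    @property
    def rundown_percent(self) -> float:
        """Percent reduction of peak ChR2 current, first beat vs last."""
        return 100.0 * (self.peak_i_chr2[0] - self.peak_i_chr2[-1]) / \
            self.peak_i_chr2[0]


def pace_train(cell, frequency: float, pulse_width: float, irradiance: float,
               total_time: float, params: ChR2Params,
               solver: SolverSettings | None = None,
               peak_window: float = 50.0,
               dt_pulse: float = 0.05, dt_rest: float = 1.0) -> PaceTrainResult:
    """Continuous optical pacing; per-beat ChR2 peak and occupancy extrema.

    ``frequency`` in Hz, ``pulse_width`` in ms, ``total_time`` in seconds.
    The model state is carried across beats with no resets, so slow
    accumulation in the light-adapted states (O2, C2) shows up as a
    rundown of the available peak current.
    """
    period = 1000.0 / frequency
    if pulse_width >= period:
        raise ValueError("pulse width must be shorter than the pacing period")
    solver = solver or SolverSettings()
    n_beats = int(round(total_time * 1000.0 / period))
    names = ("o1", "o2", "c2")
    peaks = np.empty(n_beats)
    occ_max = {n: np.empty(n_beats) for n in names}
    occ_min = {n: np.empty(n_beats) for n in names}
    y = cell.y0.copy()
    fine = min(peak_window, period)
    light = LightProtocol.single_pulse(0.0, pulse_width, irradiance,
                                       total=period)
    times = []
    for b in range(n_beats):
        try:
            res_fine = run_cell(cell, LightProtocol.single_pulse(
                0.0, pulse_width, irradiance, total=fine),
                params=params, dt_out=dt_pulse, solver=solver, y0=y)
            y_mid = res_fine.states[-1]
            if fine < period:
                res_rest = run_cell(cell, LightProtocol([], period - fine),
                                    params=params, dt_out=dt_rest,
                                    solver=solver, y0=y_mid)
                y = res_rest.states[-1]
                occ = np.vstack([res_fine.chr2_states, res_rest.chr2_states])
            else:
                y = y_mid
                occ = res_fine.chr2_states
        except RuntimeError as exc:
            return PaceTrainResult(
                np.array(times), peaks[:b],
                {n: occ_max[n][:b] for n in names},
                {n: occ_min[n][:b] for n in names},
                complete=False, message=str(exc))
        peaks[b] = np.max(np.abs(res_fine.i_chr2))
        for i, n in enumerate(names):
            occ_max[n][b] = np.max(occ[:, i])
            occ_min[n][b] = np.min(occ[:, i])
        times.append(b * period)
    return PaceTrainResult(np.array(times), peaks, occ_max, occ_min)
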