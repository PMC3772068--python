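"""Joint integration of host-cell + ChR2 state under light protocols."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ..params import ChR2Params
from ..protocols import LightProtocol, SolverSettings
from .chr2core import pack_chr2_params

__all__ = ["CellSimResult", "run_cell", "equilibrate"]


@dataclass
class CellSimResult:
    """Trajectory of a host cell with ChR2, sampled on a uniform grid."""

    time: np.ndarray                 # ms
    voltage: np.ndarray              # mV
    i_chr2: np.ndarray               # pA/pF
    currents: dict                   # name -> np.ndarray (incl. IK1)
    states: np.ndarray               # (n, n_states) full state trajectory
    chr2_states: np.ndarray          # (n, 4) view: o1, o2, c2, p
    annotations: dict = field(default_factory=dict)

    @property
    def v_max(self) -> float:
        return float(np.max(self.voltage))


def _integrate_pieces(cell, y0, pieces, params, solver, t_grid):
    """Integrate over (t0, t1, irr) pieces, sampling at t_grid points."""
    pv = pack_chr2_params(params)
    Y = np.empty((len(t_grid), cell.n_states))
    y = np.asarray(y0, float).copy()
    filled = 0
    if len(t_grid) and t_grid[0] == pieces[0][0]:
        Y[0] = y
        filled = 1
    for t0, t1, irr in pieces:
        t_eval = t_grid[(t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)]
        fun = lambda t, yy: cell.rhs(t, yy, irr, pv)
        sol = solve_ivp(fun, (t0, t1), y, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol,
                        max_step=solver.max_step,
                        t_eval=t_eval if len(t_eval) else None)
        if not sol.success:
            raise RuntimeError(
                f"cell integration failed at t={sol.t[-1]:.3f} ms: {sol.message}")
        if len(t_eval):
            Y[filled:filled + len(t_eval)] = sol.y.T
            filled += len(t_eval)
            y = sol.y[:, -1]
        else:
            y = sol.y[:, -1]
        if sol.t[-1] < t1 - 1e-9:
            sol2 = solve_ivp(fun, (sol.t[-1], t1), y, method=solver.method,
                             rtol=solver.rtol, atol=solver.atol,
                             max_step=solver.max_step)
            if not sol2.success:
                raise RuntimeError(
                    f"cell integration failed at t={sol2.t[-1]:.3f} ms: "
                    f"{sol2.message}")
            y = sol2.y[:, -1]
    return Y[:filled], y


def run_cell(cell, light: LightProtocol, duration: float | None = None,
             params: ChR2Params | None = None, dt_out: float = 0.1,
             solver: SolverSettings | None = None,
             y0: np.ndarray | None = None) -> CellSimResult:
    """Simulate a host cell under a light protocol.

    The ChR2 parameter set should be temperature-scaled to 37 C for the
    human cell models (the channel was characterised at 22 C).  With no
    light the ChR2 states stay at the dark fixed point and the solution
    is that of the unmodified cell model.
    """
    params = params or ChR2Params()
    solver = solver or SolverSettings()
    if duration is None:
        duration = light.total_duration
    if duration > light.total_duration:
        light = LightProtocol(light.segments, duration)
    t_grid = np.arange(0.0, duration + dt_out * 0.5, dt_out)
    y0 = cell.y0 if y0 is None else np.asarray(y0, float)
    Y, _ = _integrate_pieces(cell, y0, light.pieces(), params, solver, t_grid)
    t_grid = t_grid[:len(Y)]
    pv = pack_chr2_params(params)
    names = list(cell.currents(Y[0], pv))
    cur = {n: np.empty(len(Y)) for n in names}
    for i in range(len(Y)):
        ci = cell.currents(Y[i], pv)
        for n in names:
            cur[n][i] = ci[n]
    seg = light.segments[0] if light.segments else (np.nan, 0.0, 0.0)
    return CellSimResult(
        time=t_grid, voltage=Y[:, cell.v_index], i_chr2=cur["IChR2"],
        currents=cur, states=Y, chr2_states=Y[:, cell.n_cell_states:],
        annotations={"cell": cell.name, "light_on_ms": seg[0],
                     "light_off_ms": seg[0] + seg[1],
                     "irradiance_mW_mm2": seg[2], "temp_C": params.temp})


def equilibrate(cell, params: ChR2Params, duration: float = 60000.0,
                solver: SolverSettings | None = None) -> np.ndarray:
    """Evolve the cell in the dark and return (and install) the end state."""
    solver = solver or SolverSettings()
    pieces = [(0.0, duration, 0.0)]
    _, y_end = _integrate_pieces(cell, cell.y0, pieces, params, solver,
                                 np.array([]))
    cell.y0 = y_end
    return y_end
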