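"""Parameter estimation for the ChR2 model.

The fitting pipeline mirrors how the model was originally constrained:
simulate the voltage-clamp protocol grid for a candidate parameter set,
extract the empirical measures (Ip, Iss, tau_on, tau_inact, tau_off),
and minimise the weighted RMS error against target measures — first with
Boltzmann-type simulated annealing (default settings: objective limit 0,
initial temperature 1e5, reannealing interval 50, evaluation limit 1e6),
then with a greedy coordinate pattern search for high-precision local
refinement.

Temperature scaling is handled the same way: per-rate Q10 factors are
fitted so that the model's implied Q10s for four observable constraints
(tau_on, tau_off, tau_inact, Iss/Ip) match experimentally derived
constraint Q10s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .params import RATE_NAMES, ChR2Params, scale_to_temperature
from .protocols import LightProtocol, SolverSettings, run_voltage_clamp

__all__ = [
    "FreeParam", "ObjectiveSpec", "FitResult", "AnnealSettings",
    "simulate_measures", "rms_objective", "fit_annealing",
    "refine_pattern_search", "derive_q10", "fit_rate_q10s",
]

#: Objective value returned when a candidate fails to simulate.
PENALTY = 1e6

MEASURE_NAMES = ("Ip", "Iss", "tauOn", "tauInact", "tauOff")


@dataclass
class FreeParam:
    """A fitted ChR2Params field with finite box bounds."""

    name: str
    lower: float
    upper: float

    def __post_init__(self):
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)
                and self.lower < self.upper):
            raise ValueError(f"bounds for {self.name} must be finite, lo < hi")


@dataclass
class ObjectiveSpec:
    """Target measures on a (voltage, irradiance) grid plus free parameters.

    ``targets`` maps (v, irradiance) -> {measure_name: value}.  Weights
    default to 1/|target| per measure so millisecond- and pA/pF-scale
    quantities contribute commensurably.
    """

    targets: dict
    free: list
    base: ChR2Params = field(default_factory=ChR2Params)
    weights: dict | None = None
    measures: tuple = MEASURE_NAMES
    pulse_duration: float = 500.0
    dt_out: float = 0.1   # 10 kHz, the kinetics-measurement sampling rate
    solver: SolverSettings = field(
        default_factory=lambda: SolverSettings(rtol=1e-8, atol=1e-8))

    def __post_init__(self):
        valid = {f.name for f in ChR2Params.__dataclass_fields__.values()
                 if f.name not in ("q10",)}
        for fp in self.free:
            if fp.name not in valid:
                raise ValueError(f"free parameter {fp.name!r} is not a "
                                 "ChR2Params field")

    def with_params(self, x) -> ChR2Params:
        return self.base.replace(**{fp.name: xi for fp, xi in zip(self.free, x)})

    def x0(self) -> np.ndarray:
        return np.array([getattr(self.base, fp.name) for fp in self.free])

    def bounds(self) -> np.ndarray:
        return np.array([[fp.lower, fp.upper] for fp in self.free])


@dataclass
class FitResult:
    x: np.ndarray
    params: ChR2Params
    objective: float
    n_eval: int
    seed: int | None = None
    converged: bool = True
    message: str = ""
    trace: list = field(default_factory=list)


def simulate_measures(params: ChR2Params, cells, pulse_duration=500.0,
                      dt_out=0.1, solver=None) -> dict:
    """Measures per (v, irradiance) cell for a parameter set."""
    out = {}
    for v, irr in cells:
        pulse = LightProtocol.single_pulse(10.0, pulse_duration, irr,
                                           total=10.0 + pulse_duration + 650.0)
        tr = run_voltage_clamp(v, pulse, params, dt_out=dt_out, solver=solver)
        out[(v, irr)] = metrics.extract_measures(tr).as_row()
    return out


def rms_objective(candidate: ChR2Params, spec: ObjectiveSpec) -> float:
    """Weighted RMS error between simulated and target measures (>= 0).

    Simulation failures (solver breakdown, pathological fits) are mapped
    to a large finite penalty so the optimiser can move on.
    """
    try:
        sim = simulate_measures(candidate, spec.targets.keys(),
                                spec.pulse_duration, spec.dt_out, spec.solver)
    except (RuntimeError, ValueError):
        return PENALTY
    terms = []
    for cell, target in spec.targets.items():
        for name in spec.measures:
            if name not in target:
                continue
            tgt = target[name]
            got = sim[cell].get(name, math.nan)
            if not math.isfinite(got):
                return PENALTY
            w = (spec.weights or {}).get(name, 1.0 / max(abs(tgt), 1e-12))
            terms.append(w * (got - tgt))
    return float(np.sqrt(np.mean(np.square(terms))))


@dataclass
class AnnealSettings:
    """Boltzmann-type annealing schedule (published optimiser settings)."""

    initial_temp: float = 1e5
    objective_limit: float = 0.0
    reanneal_interval: int = 50
    max_evals: int = 1_000_000
    step_scale: float = 0.25     # proposal sd as a fraction of the box range


def fit_annealing(spec: ObjectiveSpec, seed: int,
                  settings: AnnealSettings | None = None,
                  objective=rms_objective, x0=None) -> FitResult:
    """Simulated annealing with a Boltzmann temperature schedule.

    T_k = T0 / ln(k + e) with the anneal counter k reset every
    ``reanneal_interval`` accepted moves; Gaussian proposals scaled by
    sqrt(T_k/T0) and reflected into the box.  Deterministic given the
    seed.  Returns the best-so-far point when the evaluation budget is
    exhausted (flagged in ``converged``/``message``).
    """
    settings = settings or AnnealSettings()
    rng = np.random.default_rng(seed)
    lob, hib = spec.bounds().T
    span = hib - lob

    def f(x):
        return objective(spec.with_params(x), spec)

    x = np.clip(spec.x0() if x0 is None else np.asarray(x0, float), lob, hib)
    fx = f(x)
    best_x, best_f = x.copy(), fx
    n_eval = 1
    k = 0
    accepted = 0
    trace = [(n_eval, best_f)]
    while n_eval < settings.max_evals:
        if best_f <= settings.objective_limit:
            return FitResult(best_x, spec.with_params(best_x), best_f, n_eval,
                             seed, True, "objective limit reached", trace)
        temp = settings.initial_temp / math.log(k + math.e)
        rel = math.sqrt(temp / settings.initial_temp)
        prop = x + rng.standard_normal(len(x)) * span * settings.step_scale * rel
        # reflect into the box
        for i in range(len(prop)):
            while prop[i] < lob[i] or prop[i] > hib[i]:
                if prop[i] < lob[i]:
                    prop[i] = 2 * lob[i] - prop[i]
                if prop[i] > hib[i]:
                    prop[i] = 2 * hib[i] - prop[i]
        fp = f(prop)
        n_eval += 1
        if fp < fx or rng.random() < math.exp(-(fp - fx) / max(temp, 1e-300)):
            x, fx = prop, fp
            accepted += 1
            if accepted % settings.reanneal_interval == 0:
                k = 0
        k += 1
        if fx < best_f:
            best_x, best_f = x.copy(), fx
            trace.append((n_eval, best_f))
    return FitResult(best_x, spec.with_params(best_x), best_f, n_eval, seed,
                     False, "evaluation budget exhausted", trace)


def refine_pattern_search(start, spec: ObjectiveSpec,
                          objective=rms_objective,
                          initial_step: float = 0.1, shrink: float = 0.5,
                          tol: float = 1e-6, max_evals: int = 10_000) -> FitResult:
    """Greedy coordinate pattern search with a shrinking step.

    ``start`` is either a parameter vector or a ChR2Params.  The step is
    a fraction of each box range; when no axial move improves the
    objective the step halves, until ``tol``.  The final objective never
    exceeds the starting one.
    """
    lob, hib = spec.bounds().T
    span = hib - lob
    if isinstance(start, ChR2Params):
        x = np.array([getattr(start, fp.name) for fp in spec.free])
    else:
        x = np.asarray(start, float).copy()
    x = np.clip(x, lob, hib)

    def f(xx):
        return objective(spec.with_params(xx), spec)

    fx = f(x)
    n_eval = 1
    step = initial_step
    trace = [(n_eval, fx)]
    while step > tol and n_eval < max_evals:
        improved = False
        for i in range(len(x)):
            for sgn in (+1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sgn * step * span[i], lob[i], hib[i])
                if cand[i] == x[i]:
                    continue
                fc = f(cand)
                n_eval += 1
                if fc < fx:
                    x, fx = cand, fc
                    improved = True
                    trace.append((n_eval, fx))
                    break
            if n_eval >= max_evals:
                break
        if not improved:
            step *= shrink
    return FitResult(x, spec.with_params(x), fx, n_eval, None, True,
                     "pattern search converged", trace)


def derive_q10(p_hot: float, p_cold: float, t_hot: float, t_cold: float,
               kind: str = "value") -> float:
    """Q10 from paired measurements at two temperatures.

    Q10 = (p_hot/p_cold)**(10/(t_hot - t_cold)).  For time constants the
    rate-equivalent convention inverts the ratio (``kind='tau'``), so a
    tau that shortens on warming yields Q10 > 1.
    """
    if p_hot <= 0 or p_cold <= 0:
        raise ValueError("parameter values must be > 0")
    if t_hot == t_cold:
        raise ValueError("temperatures must differ")
    ratio = p_hot / p_cold
    if kind == "tau":
        ratio = 1.0 / ratio
    elif kind != "value":
        raise ValueError("kind must be 'value' or 'tau'")
    return ratio ** (10.0 / (t_hot - t_cold))


CONSTRAINT_NAMES = ("tauOn", "tauOff", "tauInact", "IssIp")


def model_constraint_q10s(q10s: dict, params: ChR2Params,
                          t_hot: float = 37.0,
                          cells=((-80.0, 1.0), (-80.0, 5.5)),
                          solver=None, dt_out: float = 0.1) -> dict:
    """Model-implied constraint Q10s for a candidate per-rate Q10 set.

    Simulates the pulse protocol at the reference temperature and at
    ``t_hot`` with the candidate Q10s applied, extracts the measures at
    each grid cell, and converts each constraint's hot/cold ratio into a
    Q10 (rate-equivalent for the taus), averaged over the grid.
    """
    p_cold = params.replace(q10=dict(q10s))
    p_hot = scale_to_temperature(p_cold, t_hot)
    cold = simulate_measures(p_cold, cells, dt_out=dt_out, solver=solver)
    hot = simulate_measures(p_hot, cells, dt_out=dt_out, solver=solver)
    out = {}
    for name, kind in (("tauOn", "tau"), ("tauOff", "tau"),
                       ("tauInact", "tau")):
        vals = [derive_q10(hot[c][name], cold[c][name],
                           t_hot, params.temp, kind=kind) for c in cells]
        out[name] = float(np.mean(vals))
    vals = [derive_q10(abs(hot[c]["Iss"] / hot[c]["Ip"]),
                       abs(cold[c]["Iss"] / cold[c]["Ip"]),
                       t_hot, params.temp) for c in cells]
    out["IssIp"] = float(np.mean(vals))
    return out


def fit_rate_q10s(constraint_q10s: dict, params: ChR2Params, seed: int,
                  t_hot: float = 37.0, bounds=(0.5, 5.0),
                  settings: AnnealSettings | None = None,
                  refine: bool = True, cells=((-80.0, 1.0), (-80.0, 5.5)),
                  solver=None) -> FitResult:
    """Fit the seven per-rate Q10s to observable constraint Q10s.

    Annealing (then pattern-search refinement) over the per-rate factors,
    minimising the RMS difference between the model-implied constraint
    Q10s and the supplied ones.
    """
    missing = set(CONSTRAINT_NAMES) - set(constraint_q10s)
    if missing:
        raise ValueError(f"missing constraint Q10s: {sorted(missing)}")
    settings = settings or AnnealSettings(max_evals=400)
    free = [FreeParam(r, bounds[0], bounds[1]) for r in RATE_NAMES]

    def f_of_x(x):
        q10s = {r: xi for r, xi in zip(RATE_NAMES, x)}
        try:
            implied = model_constraint_q10s(q10s, params, t_hot, cells, solver)
        except (RuntimeError, ValueError):
            return PENALTY
        errs = [(implied[n] - constraint_q10s[n]) / constraint_q10s[n]
                for n in CONSTRAINT_NAMES]
        if not np.all(np.isfinite(errs)):
            return PENALTY
        return float(np.sqrt(np.mean(np.square(errs))))

    # fit in x-space directly: reuse the annealer through a thin adapter
    class _XSpec:
        def __init__(self):
            self.free = free

        def bounds(self):
            return np.array([[fp.lower, fp.upper] for fp in free])

        def x0(self):
            return np.array([params.q10[r] for r in RATE_NAMES])

        def with_params(self, x):
            return x

    xspec = _XSpec()
    obj = lambda x, sp: f_of_x(x)
    res = fit_annealing(xspec, seed, settings, objective=obj)
    if refine:
        res2 = refine_pattern_search(res.x, xspec, objective=obj,
                                     initial_step=0.05, tol=1e-4,
                                     max_evals=200)
        if res2.objective <= res.objective:
            res2.n_eval += res.n_eval
            res2.seed = seed
            res = res2
    q10s = {r: float(xi) for r, xi in zip(RATE_NAMES, res.x)}
    res.params = params.replace(q10=q10s)
    return res
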