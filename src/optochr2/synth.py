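"""Seeded generator of synthetic patch-clamp-like photocurrent recordings.

Emulates the whole-cell voltage-clamp data set the model was built on:
500 ms light pulses over a voltage x irradiance matrix (and optionally
S1-S2 paired pulses), sampled at 10 kHz, with additive Gaussian noise.
Ground truth comes from the noiseless simulated traces, so every stage
of the measure-extraction and fitting pipeline can be exercised offline
and checked against known generating parameters.

Gaussian white noise only: real recordings carry filtered/1-f noise and
cell-to-cell expression variability that this generator does not emulate
(a per-trace conductance scale is the only expression knob).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .params import ChR2Params
from .protocols import (DEFAULT_IRRADIANCES, DEFAULT_VOLTAGES, CurrentTrace,
                        SolverSettings, run_matrix, run_s1s2)

__all__ = ["SynthSpec", "SynthResult", "generate_traces"]


@dataclass
class SynthSpec:
    params: ChR2Params = field(default_factory=ChR2Params)
    voltages: tuple = DEFAULT_VOLTAGES
    irradiances: tuple = DEFAULT_IRRADIANCES
    s1s2_intervals: tuple = ()          # ms; empty = no paired pulses
    s1s2_irradiance: float = 1.6
    noise_sd_frac: float = 0.05         # sd as a fraction of |peak|, per trace
    noise_sd_abs: float = 0.0           # pA/pF, absolute floor
    baseline_offset: float = 0.0        # pA/pF, constant offset
    g_scale: float = 1.0                # per-trace conductance scale
    dt_out: float = 0.1                 # ms (10 kHz)
    seed: int = 0
    solver: SolverSettings | None = None

    def __post_init__(self):
        if self.noise_sd_frac < 0 or self.noise_sd_abs < 0:
            raise ValueError("noise sd must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SynthResult:
    traces: dict                 # (v, irr) -> noisy CurrentTrace
    clean: dict                  # (v, irr) -> noiseless CurrentTrace
    truth: pd.DataFrame          # measures extracted from the clean traces
    s1s2: list = field(default_factory=list)   # (interval, tr1, tr2) noisy

    def write(self, directory: str | Path) -> None:
        from . import io
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (v, irr), tr in self.traces.items():
            io.write_trace(directory / f"trace_v{v:+.0f}_i{irr:g}.csv", tr)
        io.write_measures_table(directory / "ground_truth.csv", self.truth)


def generate_traces(spec: SynthSpec) -> SynthResult:
    """Simulate the protocol grid, add seeded noise, extract ground truth."""
    rng = np.random.default_rng(spec.seed)
    params = spec.params.replace(g_chr2=spec.params.g_chr2 * spec.g_scale)
    clean = run_matrix(spec.voltages, spec.irradiances, params,
                       dt_out=spec.dt_out, solver=spec.solver)

    rows = []
    noisy = {}
    for (v, irr), tr in clean.items():
        m = metrics.extract_measures(tr)
        rows.append({"v_mV": v, "irradiance_mW_mm2": irr, **m.as_row()})
        sd = spec.noise_sd_frac * np.max(np.abs(tr.current)) + spec.noise_sd_abs
        noise = rng.normal(0.0, sd, len(tr.current)) if sd > 0 else 0.0
        noisy[(v, irr)] = CurrentTrace(
            tr.time, tr.current + noise + spec.baseline_offset,
            dict(tr.annotations, noise_sd=float(sd),
                 baseline_offset=spec.baseline_offset, seed=spec.seed))

    s1s2 = []
    for interval in spec.s1s2_intervals:
        tr1, tr2 = run_s1s2(spec.voltages[0], spec.s1s2_irradiance, interval,
                            params, dt_out=spec.dt_out, solver=spec.solver)
        pair = []
        for tr in (tr1, tr2):
            sd = spec.noise_sd_frac * np.max(np.abs(tr.current)) + spec.noise_sd_abs
            noise = rng.normal(0.0, sd, len(tr.current)) if sd > 0 else 0.0
            pair.append(CurrentTrace(tr.time, tr.current + noise,
                                     dict(tr.annotations, seed=spec.seed)))
        s1s2.append((interval, *pair))

    truth = pd.DataFrame(rows)
    return SynthResult(traces=noisy, clean=clean, truth=truth, s1s2=s1s2)
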