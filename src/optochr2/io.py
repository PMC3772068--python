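"""Delimited-text file formats: traces, measure tables, configs.

Traces are CSV with a commented ``# key: value`` header carrying the
protocol annotations, then ``time_ms,current_pA_per_pF`` rows.  Measure
tables are plain CSV, one row per (voltage, irradiance) protocol cell.
Parameter sets and run configurations are YAML.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ChR2Params
from .protocols import CurrentTrace, SolverSettings

__all__ = [
    "write_trace", "read_trace", "write_measures_table",
    "read_measures_table", "RunConfig", "load_config",
    "default_params", "default_params_37c",
]

_DATA = Path(__file__).parent / "data"


def default_params() -> ChR2Params:
    """The bundled room-temperature (22 C) parameter set."""
    return ChR2Params.from_yaml(_DATA / "chr2_22c.yaml")


def default_params_37c() -> ChR2Params:
    """The bundled 37 C Q10-scaled parameter set."""
    return ChR2Params.from_yaml(_DATA / "chr2_37c.yaml")


def write_trace(path: str | Path, trace: CurrentTrace) -> None:
    with open(path, "w") as fh:
        for key in sorted(trace.annotations):
            fh.write(f"# {key}: {trace.annotations[key]!r}\n")
        fh.write("time_ms,current_pA_per_pF\n")
        for t, c in zip(trace.time, trace.current):
            fh.write(f"{t:.6g},{c:.10g}\n")


def read_trace(path: str | Path) -> CurrentTrace:
    annotations = {}
    rows_t, rows_c = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                try:
                    annotations[key.strip()] = ast.literal_eval(val.strip())
                except (ValueError, SyntaxError):
                    annotations[key.strip()] = val.strip()
            elif line[0].isdigit() or line[0] in "+-.":
                t, _, c = line.partition(",")
                rows_t.append(float(t))
                rows_c.append(float(c))
    return CurrentTrace(np.array(rows_t), np.array(rows_c), annotations)


MEASURE_COLUMNS = ("v_mV", "irradiance_mW_mm2", "Ip", "Iss", "tauOn",
                   "tauInact", "tauOff")


def write_measures_table(path: str | Path, table: pd.DataFrame) -> None:
    missing = set(MEASURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measures table missing columns: {sorted(missing)}")
    table.to_csv(path, index=False)


def read_measures_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(MEASURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measures table missing columns: {sorted(missing)}")
    return table


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled."""

    params: ChR2Params
    solver: SolverSettings
    seed: int = 0
    temp: float | None = None
    output_dir: Path = Path(".")
    protocol: dict = field(default_factory=dict)


_CONFIG_KEYS = {"params_file", "params", "rtol", "atol", "method",
                "max_step", "seed", "temp", "output_dir", "protocol"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; missing solver tolerances default
    to the 1e-10 integration tolerances used throughout.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    if "params_file" in raw:
        pfile = Path(raw["params_file"])
        if not pfile.is_absolute():
            pfile = Path(path).parent / pfile
        if not pfile.exists():
            raise FileNotFoundError(f"params_file not found: {pfile}")
        params = ChR2Params.from_yaml(pfile)
    elif "params" in raw:
        params = ChR2Params.from_dict(raw["params"])
    else:
        params = default_params()
    solver = SolverSettings(rtol=float(raw.get("rtol", 1e-10)),
                            atol=float(raw.get("atol", 1e-10)),
                            method=raw.get("method", "LSODA"),
                            max_step=float(raw.get("max_step", np.inf)))
    cfg = RunConfig(params=params, solver=solver,
                    seed=int(raw.get("seed", 0)),
                    temp=raw.get("temp"),
                    output_dir=Path(raw.get("output_dir", ".")),
                    protocol=raw.get("protocol", {}) or {})
    if cfg.temp is not None:
        from .params import scale_to_temperature
        cfg.params = scale_to_temperature(cfg.params, float(cfg.temp))
    return cfg
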