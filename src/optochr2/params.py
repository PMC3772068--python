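"""Parameter set for the four-state ChR2(H134R) photocycle model.

Units convention throughout the package: time in ms, voltage in mV,
irradiance in mW/mm^2, rates in ms^-1.  Conductance density is mS/cm^2;
with a membrane capacitance of 1 uF/cm^2 the current mS/cm^2 * mV comes
out in uA/uF, numerically identical to pA/pF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: The seven explicit kinetic rates that carry an individual Q10 factor.
RATE_NAMES = ("k1", "k2", "gd1", "gd2", "gr", "e12", "e21")

#: Default per-rate Q10 factors.  The light-absorption steps k1/k2 are
#: photophysical and essentially athermal (Q10 = 1); the thermal
#: conformational transitions are given Q10 values in the classical
#: ion-channel range (2-3), with the O2->O1 return faster-scaling than
#: O1->O2 so that warming enlarges the sustained fraction of the current,
#: the direction seen experimentally.
DEFAULT_Q10 = {
    "k1": 1.0,
    "k2": 1.0,
    "gd1": 2.3,
    "gd2": 2.3,
    "gr": 2.3,
    "e12": 1.5,
    "e21": 2.5,
}


@dataclass
class ChR2Params:
    """All constants of the four-state ChR2(H134R) model.

    Defaults are the published room-temperature (22 C) values, with one
    deliberate exception: ``gr_pref`` uses 4.34587e-5 ms^-1 rather than
    the printed 4.34587e5.  The printed prefactor implies sub-microsecond
    recovery from inactivation, contradicting the seconds-scale recovery
    measured with the S1-S2 protocol and the stated Gr ~ 1/tau_R
    relationship; the adopted value gives tau_R(-80 mV) ~ 4.2 s, on the
    observed scale.
    """

    # conductance and driving force
    g_chr2: float = 0.4          # mS/cm^2, maximal conductance (scaling)
    e_rev: float = 0.0           # mV, reversal potential
    gamma: float = 0.1           # O2/O1 conductance ratio
    # rectification function G(V)*(V - E) = rect_a - rect_b*exp(-V/rect_vs)
    rect_a: float = 10.6408
    rect_b: float = 14.6408
    rect_vs: float = 42.7671     # mV

    # photophysics
    eps1: float = 0.8535         # quantum efficiency, C1 photon absorption
    eps2: float = 0.14           # quantum efficiency, C2 photon absorption
    sigma_ret: float = 12e-20    # m^2, retinal absorption cross-section
    lambda_max: float = 470.0    # nm
    w_loss: float = 0.77         # photon-loss divisor
    hc: float = 1.986446e-25     # kg m^3 / s^2, Planck constant x c
    flux_coeff: float = 0.0006   # ms^-1 per (mW/mm^2 * nm); = sigma_ret/hc in these units
    tau_chr2: float = 1.3        # ms, retinal activation time constant
    theta_scale: float = 100.0   # maps irradiance to the S0 sigmoid argument

    # dark and light-graded inter-open rates, ms^-1
    e12_dark: float = 0.011
    e21_dark: float = 0.008
    log_c1_12: float = 0.005     # ms^-1, log-irradiance coefficient of e12
    log_c1_21: float = 0.004     # ms^-1, log-irradiance coefficient of e21
    log_c2: float = 0.024        # mW/mm^2, irradiance scale of the log terms

    # closing / recovery rates
    gd2: float = 0.05            # ms^-1, O2 -> C2
    gd1_base: float = 0.075      # ms^-1, Gd1(V) offset
    gd1_amp: float = 0.043       # ms^-1, Gd1(V) tanh amplitude
    gd1_v0: float = 20.0         # mV, Gd1(V) midpoint (tanh((V+v0)/vs))
    gd1_vs: float = -20.0        # mV, Gd1(V) slope (negative: slower at depolarized V)
    gr_pref: float = 4.34587e-5  # ms^-1, Gr(V) prefactor (see class docstring)
    gr_slope: float = 0.0211539274  # mV^-1, Gr = gr_pref * exp(-gr_slope*V)

    # multiplicative temperature factors applied to k1/k2 (photon-flux path)
    k1_scale: float = 1.0
    k2_scale: float = 1.0

    # temperature handling
    q10: dict = field(default_factory=lambda: dict(DEFAULT_Q10))
    temp_ref: float = 22.0       # C, temperature at which the rates are stated
    temp: float = 22.0           # C, operating temperature

    def __post_init__(self) -> None:
        if self.g_chr2 < 0:
            raise ValueError("g_chr2 must be >= 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        for name in ("eps1", "eps2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.w_loss <= 0:
            raise ValueError("w_loss must be > 0")
        if self.tau_chr2 <= 0:
            raise ValueError("tau_chr2 must be > 0")
        for name in ("e12_dark", "e21_dark", "log_c1_12", "log_c1_21",
                     "log_c2", "gd2", "gr_pref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(RATE_NAMES) - set(self.q10)
        if missing:
            raise ValueError(f"q10 missing rates: {sorted(missing)}")
        if any(self.q10[r] <= 0 for r in RATE_NAMES):
            raise ValueError("all q10 factors must be > 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        q10 = d.pop("q10")
        for r in RATE_NAMES:
            d[f"q10_{r}"] = q10[r]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChR2Params":
        d = dict(d)
        q10 = {r: d.pop(f"q10_{r}", DEFAULT_Q10[r]) for r in RATE_NAMES}
        if "q10" in d:
            q10.update(d.pop("q10"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown ChR2 parameter keys: {sorted(unknown)}")
        return cls(q10=q10, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChR2Params":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "ChR2Params":
        return dataclasses.replace(self, **kwargs)


def temperature_factors(params: ChR2Params, temp: float) -> dict:
    """Per-rate multipliers q10**((temp - params.temp)/10)."""
    ex = (temp - params.temp) / 10.0
    return {r: params.q10[r] ** ex for r in RATE_NAMES}


def scale_to_temperature(params: ChR2Params, temp: float) -> ChR2Params:
    """Return a parameter set whose seven rates are Q10-scaled to ``temp``.

    Rate *functions* are scaled as a whole (both coefficients of Gd1(V),
    the prefactor of Gr(V), and both the dark offset and log-irradiance
    coefficient of e12/e21), so that the multiplicative factor applies at
    every voltage and irradiance.  k1 and k2 are scaled through the
    ``k1_scale``/``k2_scale`` multipliers.  Scaling is relative to the
    set's current operating temperature, so scaling to ``params.temp``
    returns an identical set and 22 -> 37 -> 22 round-trips.
    """
    f = temperature_factors(params, temp)
    return params.replace(
        k1_scale=params.k1_scale * f["k1"],
        k2_scale=params.k2_scale * f["k2"],
        gd1_base=params.gd1_base * f["gd1"],
        gd1_amp=params.gd1_amp * f["gd1"],
        gd2=params.gd2 * f["gd2"],
        gr_pref=params.gr_pref * f["gr"],
        e12_dark=params.e12_dark * f["e12"],
        log_c1_12=params.log_c1_12 * f["e12"],
        e21_dark=params.e21_dark * f["e21"],
        log_c1_21=params.log_c1_21 * f["e21"],
        temp=temp,
    )
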