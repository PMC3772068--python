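"""Extraction of the empirical photocurrent measures from current traces.

Six measures summarise a 500 ms light-pulse response and the paired-pulse
recovery experiment:

* ``i_peak`` -- extremal current during the light pulse (signed, pA/pF);
* ``i_ss``   -- mean current 400-450 ms after light onset;
* ``tau_on`` -- activation time constant, rising mono-exponential fit over
  the 10 ms leading up to the peak;
* ``tau_inact`` -- inactivation (sag) time constant, decaying fit over
  10-110 ms after the peak;
* ``tau_off`` -- deactivation time constant, decaying fit over 500-600 ms
  after the peak (the light is off by then for a 500 ms pulse);
* ``tau_r``  -- recovery-from-inactivation time constant from the
  IP2/IP1-vs-interval curve of the S1-S2 protocol, read off at the
  1 - 1/e ~ 0.632 crossing after cubic-spline interpolation.

All fit windows are anchored to the *peak time* on the median-filtered
trace, and are configurable.  Traces are median-filtered before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.optimize import brentq, curve_fit

from .protocols import CurrentTrace

__all__ = [
    "EmpiricalMeasures",
    "RecoveryMeasures",
    "MonoExpFit",
    "median_filter_trace",
    "fit_monoexp",
    "extract_measures",
    "recovery_curve",
    "MeasureWindows",
]


@dataclass
class MonoExpFit:
    tau: float          # ms
    amplitude: float
    offset: float
    rms: float
    ok: bool = True
    message: str = ""


@dataclass
class EmpiricalMeasures:
    i_peak: float = math.nan     # pA/pF, signed
    i_ss: float = math.nan       # pA/pF, signed
    tau_on: float = math.nan     # ms
    tau_inact: float = math.nan  # ms
    tau_off: float = math.nan    # ms
    t_peak: float = math.nan     # ms, location of the peak
    fits: dict = field(default_factory=dict)   # name -> MonoExpFit
    flags: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {"Ip": self.i_peak, "Iss": self.i_ss, "tauOn": self.tau_on,
                "tauInact": self.tau_inact, "tauOff": self.tau_off}


@dataclass
class RecoveryMeasures:
    intervals: np.ndarray        # ms
    ratio_ip: np.ndarray         # IP2/IP1 per interval
    tau_r: float                 # ms, 0.632 spline crossing
    tau_r_exp: float = math.nan  # ms, mono-exponential fit alternative
    fit: MonoExpFit | None = None


@dataclass
class MeasureWindows:
    """Fit/averaging windows, ms, relative to peak time (taus) or onset (Iss)."""

    on: tuple = (-10.0, 0.0)
    inact: tuple = (10.0, 110.0)
    off: tuple = (500.0, 600.0)
    ss: tuple = (400.0, 450.0)
    baseline: tuple = (-10.0, 0.0)   # relative to onset, for baseline subtraction
    #: earliest start of the activation window, ms after light onset; guards
    #: the sigmoidal retinal-activation delay (~2*tau_ChR2), which is not part
    #: of the channel-opening exponential being fitted
    on_guard: float = 2.6


def median_filter_trace(trace: CurrentTrace, window: int = 5) -> CurrentTrace:
    """Median-filter the current with edge replication at the endpoints."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median filter window must be odd and >= 1")
    filtered = median_filter(trace.current, size=window, mode="nearest")
    return CurrentTrace(trace.time, filtered, dict(trace.annotations),
                        states=trace.states)


def _loglin_tau_guess(t, y, form):
    """Log-linear regression initial guess for the time constant."""
    if form == "decaying":
        z = y - y[-1]
    else:
        z = y[-1] - y
    sign = np.sign(z[np.argmax(np.abs(z))]) or 1.0
    z = sign * z
    good = z > max(1e-12, 1e-6 * np.max(z))
    if good.sum() < 3:
        return None
    slope = np.polyfit(t[good], np.log(z[good]), 1)[0]
    if slope >= 0:
        return None
    return -1.0 / slope


def fit_monoexp(time, current, form: str = "decaying",
                tau_bounds: tuple = (0.01, 1e5)) -> MonoExpFit:
    """Least-squares mono-exponential fit of a trace segment.

    ``decaying``: y = A*exp(-t/tau) + B;  ``rising``: y = A*(1-exp(-t/tau)) + B,
    with t measured from the start of the segment.  tau is kept positive by
    bounds.  A trust-region solver (scipy ``trf``) is used; initial tau from
    a log-linear regression, A and B from the segment endpoints.
    """
    t = np.asarray(time, float)
    y = np.asarray(current, float)
    if len(t) < 5:
        return MonoExpFit(math.nan, math.nan, math.nan, math.nan, False,
                          "segment too short")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t0 = t[0]
    tt = t - t0
    span = np.ptp(y)
    if span < 1e-12 * max(1.0, np.max(np.abs(y))):
        return MonoExpFit(math.nan, math.nan, math.nan, 0.0, False,
                          "degenerate (constant) segment")

    if form == "decaying":
        model = lambda x, a, tau, b: a * np.exp(-x / tau) + b
        a0, b0 = y[0] - y[-1], y[-1]
    elif form == "rising":
        model = lambda x, a, tau, b: a * (1.0 - np.exp(-x / tau)) + b
        a0, b0 = y[-1] - y[0], y[0]
    else:
        raise ValueError("form must be 'rising' or 'decaying'")

    tau0 = _loglin_tau_guess(tt, y, form) or (tt[-1] - tt[0]) / 3.0
    tau0 = float(np.clip(tau0, *tau_bounds))
    lo = [-np.inf, tau_bounds[0], -np.inf]
    hi = [np.inf, tau_bounds[1], np.inf]
    try:
        popt, _ = curve_fit(model, tt, y, p0=[a0, tau0, b0],
                            bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000)
    except Exception as exc:  # non-convergence is flagged, not raised
        return MonoExpFit(math.nan, math.nan, math.nan, math.nan, False,
                          f"fit failed: {exc}")
    resid = y - model(tt, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return MonoExpFit(tau=float(popt[1]), amplitude=float(popt[0]),
                      offset=float(popt[2]), rms=rms)


def _window(trace, t0, t1):
    m = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
    return trace.time[m], trace.current[m]


def extract_measures(trace: CurrentTrace, light_on: float | None = None,
                     light_off: float | None = None,
                     windows: MeasureWindows | None = None,
                     median_window: int = 5,
                     subtract_baseline: bool = False) -> EmpiricalMeasures:
    """Extract Ip, Iss, tau_on, tau_inact and tau_off from a pulse trace.

    The peak is located on the median-filtered trace within the light
    pulse; all three fit windows are positioned relative to the peak
    time.  Non-converging fits are flagged on the returned object rather
    than raised.  ``subtract_baseline`` removes the mean pre-light
    current (for experimental traces; simulated traces are already
    baseline-free densities).
    """
    windows = windows or MeasureWindows()
    ann = trace.annotations
    light_on = ann.get("light_on_ms") if light_on is None else light_on
    light_off = ann.get("light_off_ms") if light_off is None else light_off
    if light_on is None or light_off is None:
        raise ValueError("light_on/light_off must be given or annotated")
    filt = median_filter_trace(trace, median_window)
    if subtract_baseline:
        tb, yb = _window(filt, light_on + windows.baseline[0],
                         light_on + windows.baseline[1])
        if len(yb):
            filt = CurrentTrace(filt.time, filt.current - np.mean(yb),
                                dict(filt.annotations))

    m = EmpiricalMeasures()
    t_peak, i_peak = filt.peak(light_on, light_off)
    # anchor on the *first* attainment of the extremum so plateau-shaped
    # responses (monotone rise, no sag) get a well-defined peak time
    win = (filt.time >= light_on) & (filt.time <= light_off)
    attained = win & (np.abs(filt.current) >= 0.999 * abs(i_peak))
    if attained.any():
        k = np.flatnonzero(attained)[0]
        t_peak, i_peak = float(filt.time[k]), float(filt.current[k])
    m.t_peak, m.i_peak = t_peak, i_peak

    t_ss, y_ss = _window(filt, light_on + windows.ss[0], light_on + windows.ss[1])
    if len(y_ss):
        m.i_ss = float(np.mean(y_ss))
    else:
        m.flags.append("ss window outside trace")

    for name, (w0, w1), form in (
            ("tau_on", windows.on, "rising"),
            ("tau_inact", windows.inact, "decaying"),
            ("tau_off", windows.off, "decaying")):
        lo, hi = t_peak + w0, t_peak + w1
        if name == "tau_on":
            # the activation segment cannot start before the light does,
            # nor inside the retinal-activation delay; for very fast
            # responses the guard never consumes more than half the rise
            guard = min(windows.on_guard, 0.5 * (t_peak - light_on))
            lo = max(lo, light_on + guard)
        seg_t, seg_y = _window(filt, lo, hi)
        fit = fit_monoexp(seg_t, seg_y, form)
        m.fits[name] = fit
        if fit.ok:
            setattr(m, name, fit.tau)
        else:
            m.flags.append(f"{name}: {fit.message}")
    return m


def recovery_curve(intervals, ip1, ip2,
                   crossing: float = 1.0 - 1.0 / math.e) -> RecoveryMeasures:
    """Recovery-from-inactivation measures from S1-S2 peak pairs.

    ``ratio_ip = IP2/IP1`` per interval; ``tau_r`` is the interval at
    which the cubic-spline-interpolated ratio curve crosses
    1 - 1/e ~ 0.632.  A mono-exponential fit of the ratio curve is also
    provided (``tau_r_exp``).  If the sampled curve never crosses the
    threshold the spline is not extrapolated and an error is raised.
    """
    intervals = np.asarray(intervals, float)
    ip1 = np.asarray(ip1, float)
    ip2 = np.asarray(ip2, float)
    if len(intervals) < 3:
        raise ValueError("need >= 3 intervals")
    order = np.argsort(intervals)
    intervals, ip1, ip2 = intervals[order], ip1[order], ip2[order]
    ratio = np.abs(ip2) / np.abs(ip1)

    spline = CubicSpline(intervals, ratio)
    f = lambda x: float(spline(x)) - crossing
    lo = None
    for a, b in zip(intervals[:-1], intervals[1:]):
        if f(a) <= 0 <= f(b) or f(b) <= 0 <= f(a):
            lo = (a, b)
            break
    if f(intervals[0]) >= 0:
        raise ValueError("recovery already above the crossing at the "
                         "shortest interval; no tau_r within range")
    if lo is None:
        raise ValueError("recovery curve does not cross the threshold "
                         "within the sampled intervals; refusing to "
                         "extrapolate")
    tau_r = brentq(f, *lo)

    fit = fit_monoexp(intervals, ratio, form="rising")
    return RecoveryMeasures(intervals=intervals, ratio_ip=ratio,
                            tau_r=float(tau_r),
                            tau_r_exp=fit.tau if fit.ok else math.nan,
                            fit=fit)


def recovery_from_s1s2(results, **kwargs) -> RecoveryMeasures:
    """Convenience wrapper over a list of (interval, trace1, trace2)."""
    intervals, ip1, ip2 = [], [], []
    for interval, tr1, tr2 in results:
        a1 = tr1.annotations
        a2 = tr2.annotations
        ip1.append(tr1.peak(a1["light_on_ms"], a1["light_off_ms"])[1])
        ip2.append(tr2.peak(a2["light_on_ms"], a2["light_off_ms"])[1])
        intervals.append(interval)
    return recovery_curve(intervals, ip1, ip2, **kwargs)
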