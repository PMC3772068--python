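"""Empirical-measure extraction: filtering, exponential fits, recovery."""

import numpy as np
import pytest

from optochr2 import metrics as M
from optochr2.protocols import CurrentTrace, run_s1s2


def _trace(t, y, **ann):
    return CurrentTrace(np.asarray(t, float), np.asarray(y, float), ann)


class TestMedianFilter:
    def test_window_one_is_identity(self):
        tr = _trace(np.arange(10.0), np.sin(np.arange(10.0)))
        out = M.median_filter_trace(tr, 1)
        assert np.array_equal(out.current, tr.current)

    def test_single_sample_spike_removed(self):
        y = np.zeros(50)
        y[20] = 100.0
        out = M.median_filter_trace(_trace(np.arange(50.0), y), 5)
        assert out.current[20] == 0.0

    def test_even_window_rejected(self):
        tr = _trace(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            M.median_filter_trace(tr, 4)

    def test_monotone_ramp_unchanged_inside(self):
        y = np.arange(10.0)
        out = M.median_filter_trace(_trace(np.arange(10.0), y), 3)
        # brute-force median with edge replication
        padded = np.r_[y[0], y, y[-1]]
        expected = np.array([np.median(padded[i:i + 3]) for i in range(10)])
        assert np.array_equal(out.current, expected)
        assert np.array_equal(out.current[1:-1], y[1:-1])


class TestMonoExpFit:
    def test_noiseless_decay_recovered_exactly(self):
        t = np.linspace(0.0, 50.0, 400)
        y = 3.0 * np.exp(-t / 7.0) + 1.0
        fit = M.fit_monoexp(t, y, "decaying")
        assert fit.ok
        assert fit.tau == pytest.approx(7.0, abs=1e-4)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-6)
        assert fit.offset == pytest.approx(1.0, rel=1e-6)

    def test_sign_flip_leaves_tau_unchanged(self):
        t = np.linspace(0.0, 50.0, 300)
        y = 3.0 * np.exp(-t / 7.0) + 1.0
        up = M.fit_monoexp(t, y, "decaying")
        dn = M.fit_monoexp(t, -y, "decaying")
        assert dn.tau == pytest.approx(up.tau, rel=1e-8)
        assert dn.amplitude == pytest.approx(-up.amplitude, rel=1e-8)

    def test_rising_form(self):
        t = np.linspace(0.0, 30.0, 200)
        y = -5.0 * (1.0 - np.exp(-t / 2.0)) - 0.5
        fit = M.fit_monoexp(t, y, "rising")
        assert fit.ok and fit.tau == pytest.approx(2.0, rel=1e-6)

    def test_constant_segment_flagged(self):
        fit = M.fit_monoexp(np.arange(10.0), np.ones(10), "decaying")
        assert not fit.ok
        assert "degenerate" in fit.message

    def test_noisy_tau_recovery_over_many_seeds(self):
        """Median fitted tau within 2% of truth at 5% amplitude noise."""
        t = np.linspace(0.0, 50.0, 500)
        clean = -4.0 * np.exp(-t / 7.0) - 1.0
        taus = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0.0, 0.05 * 4.0, len(t))
            fit = M.fit_monoexp(t, noisy, "decaying")
            if fit.ok:
                taus.append(fit.tau)
        assert len(taus) > 190
        assert np.median(taus) == pytest.approx(7.0, rel=0.02)


class TestExtractMeasures:
    def test_known_rising_time_constant(self):
        dt = 0.1
        t = np.arange(0.0, 700.0, dt)
        y = np.zeros_like(t)
        after = t >= 10.0
        y[after] = -1.0 * (1.0 - np.exp(-(t[after] - 10.0) / 2.0))
        m = M.extract_measures(_trace(t, y), light_on=10.0, light_off=510.0)
        assert m.tau_on == pytest.approx(2.0, rel=0.01)
        assert m.i_peak == pytest.approx(-1.0, abs=1e-3)

    def test_flat_trace_flags_inactivation_fit(self):
        t = np.arange(0.0, 700.0, 0.5)
        y = np.where(t >= 10.0, -2.0, -2.0)   # constant everywhere
        m = M.extract_measures(_trace(t, y), light_on=10.0, light_off=510.0)
        assert m.i_peak == m.i_ss
        assert not m.fits["tau_inact"].ok

    def test_simulated_trace_against_loglinear_oracle(self, pulse_trace):
        """Fitted tau_inact agrees with an independent log-linear regression
        on the same decay segment."""
        tr = pulse_trace(-80.0, 5.5)
        m = M.extract_measures(tr)
        assert 0.0 < abs(m.i_ss) < abs(m.i_peak)
        assert m.tau_inact < 500.0
        lo, hi = m.t_peak + 10.0, m.t_peak + 110.0
        mask = (tr.time >= lo) & (tr.time <= hi)
        seg_t, seg_y = tr.time[mask], tr.current[mask]
        # decay towards the asymptote estimated from the fit offset
        z = seg_y - m.fits["tau_inact"].offset
        sign = np.sign(z[0])
        good = sign * z > 1e-6
        slope = np.polyfit(seg_t[good], np.log(sign * z[good]), 1)[0]
        tau_oracle = -1.0 / slope
        assert m.tau_inact == pytest.approx(tau_oracle, rel=0.05)

    def test_time_shift_invariance(self, params):
        dt = 0.1
        t = np.arange(0.0, 700.0, dt)
        y = np.zeros_like(t)
        after = t >= 10.0
        rel = t[after] - 10.0
        y[after] = -3.0 * (1 - np.exp(-rel / 2.0)) * (
            0.4 + 0.6 * np.exp(-rel / 30.0))
        m0 = M.extract_measures(_trace(t, y), light_on=10.0, light_off=510.0)
        shift = 250.0
        m1 = M.extract_measures(_trace(t + shift, y), light_on=10.0 + shift,
                                light_off=510.0 + shift)
        assert m1.i_peak == pytest.approx(m0.i_peak, rel=1e-9)
        assert m1.tau_inact == pytest.approx(m0.tau_inact, rel=1e-6)
        assert m1.t_peak == pytest.approx(m0.t_peak + shift, abs=1e-9)

    def test_baseline_subtraction(self):
        t = np.arange(0.0, 700.0, 0.5)
        y = np.full_like(t, 5.0)
        after = t >= 10.0
        y[after] += -2.0 * (1 - np.exp(-(t[after] - 10.0) / 3.0))
        m = M.extract_measures(_trace(t, y), light_on=10.0, light_off=510.0,
                               subtract_baseline=True)
        assert m.i_peak == pytest.approx(-2.0, abs=0.01)


class TestRecoveryCurve:
    def test_known_recovery_time_constant(self):
        intervals = np.array([500.0, 1000.0, 3000.0, 7000.0, 15000.0])
        ratio = 1.0 - np.exp(-intervals / 4000.0)
        rec = M.recovery_curve(intervals, -np.ones_like(ratio), -ratio)
        assert rec.tau_r == pytest.approx(4000.0, rel=0.05)
        assert rec.tau_r_exp == pytest.approx(4000.0, rel=0.01)

    def test_full_recovery_has_no_crossing(self):
        intervals = [500.0, 1000.0, 3000.0]
        with pytest.raises(ValueError):
            M.recovery_curve(intervals, [-1.0] * 3, [-1.0] * 3)

    def test_dark_recovery_matches_inverse_gr(self, params, fast_solver):
        """The mono-exponential recovery time constant at -80 mV matches
        1/Gr(-80): the dark interval recovers C2 -> C1 at rate Gr alone."""
        from optochr2.kinetics import voltage_rates
        results = []
        for interval in (500.0, 1000.0, 3000.0, 7000.0, 15000.0):
            tr1, tr2 = run_s1s2(-80.0, 1.6, interval, params, dt_out=1.0,
                                solver=fast_solver)
            results.append((interval, tr1, tr2))
        rec = M.recovery_from_s1s2(results)
        gr = voltage_rates(-80.0, params)["gr"]
        assert rec.tau_r_exp == pytest.approx(1.0 / gr, rel=0.10)
        assert 0.0 < rec.tau_r < rec.intervals[-1]


def test_tau_off_is_light_insensitive(params, pulse_trace):
    """Coefficient of variation of tau_off across irradiances under 10%."""
    taus = [M.extract_measures(pulse_trace(-80.0, irr)).tau_off
            for irr in (0.34, 1.0, 3.0, 5.5)]
    cv = np.std(taus) / np.mean(taus)
    assert cv < 0.10
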