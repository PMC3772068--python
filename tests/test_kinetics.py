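"""Rate laws, rectification, current equation and photocycle dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from optochr2 import kinetics as K
from optochr2.params import ChR2Params
from optochr2.protocols import LightProtocol, integrate_chr2


class TestPhotonFlux:
    def test_zero_light(self, params):
        assert K.photon_flux(0.0, params) == 0.0

    def test_linear_in_irradiance(self, params):
        assert K.photon_flux(2.2, params) == pytest.approx(
            2.0 * K.photon_flux(1.1, params), rel=1e-14)

    def test_value_at_max_irradiance(self, params):
        # 0.0006 * 5.5 * 470 / 0.77, cross-checked against the
        # sigma_ret/hc formulation with unit conversions
        f = K.photon_flux(5.5, params)
        assert f == pytest.approx(2.014285714, rel=1e-9)
        # 5.5 mW/mm^2 = 5500 W/m^2; wavelength 470 nm; result in s^-1
        sigma_form = (params.sigma_ret / params.hc) * 470e-9 * 5500.0 / 0.77
        assert f == pytest.approx(sigma_form * 1e-3, rel=0.01)

    def test_negative_irradiance_rejected(self, params):
        with pytest.raises(ValueError):
            K.photon_flux(-1.0, params)


class TestLightRates:
    def test_dark_rates(self, params):
        r = K.light_rates(0.0, 1.0, params)
        assert r["k1"] == 0.0 and r["k2"] == 0.0
        assert r["e12"] == pytest.approx(0.011)
        assert r["e21"] == pytest.approx(0.008)

    def test_log_term_at_its_scale_irradiance(self, params):
        r = K.light_rates(0.024, 1.0, params)
        assert r["e12"] == pytest.approx(0.011 + 0.005 * math.log(2), rel=1e-12)
        assert r["e21"] == pytest.approx(0.008 + 0.004 * math.log(2), rel=1e-12)

    def test_inactive_retinal_blocks_opening(self, params):
        r = K.light_rates(5.5, 0.0, params)
        assert r["k1"] == 0.0 and r["k2"] == 0.0

    @given(st.floats(0.0, 10.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_all_rates_nonnegative(self, irr, p):
        r = K.light_rates(irr, p, ChR2Params())
        assert all(v >= 0.0 for v in r.values())


class TestVoltageRates:
    def test_gd1_inflection(self, params):
        assert K.voltage_rates(-20.0, params)["gd1"] == pytest.approx(0.075)

    def test_gd1_saturation(self, params):
        assert K.voltage_rates(-1000.0, params)["gd1"] == pytest.approx(0.118)

    def test_gr_at_minus80(self, params):
        # with the adopted prefactor, tau_R(-80) ~ 4.2 s
        gr = K.voltage_rates(-80.0, params)["gr"]
        assert gr == pytest.approx(2.36e-4, rel=0.01)

    def test_monotonicity_over_physiological_range(self, params):
        v = np.linspace(-100, 60, 200)
        gd1 = [K.voltage_rates(x, params)["gd1"] for x in v]
        gr = [K.voltage_rates(x, params)["gr"] for x in v]
        assert np.all(np.diff(gd1) <= 1e-15)        # non-increasing
        assert np.all(np.diff(gr) < 0)              # strictly decreasing
        assert min(gd1) > 0 and min(gr) > 0


class TestActivationSigmoid:
    def test_midpoint(self):
        assert K.s0(0.1) == pytest.approx(0.5)

    def test_saturation(self):
        assert K.s0(100.0) == pytest.approx(1.0)

    def test_dark_value(self):
        assert K.s0(0.0) == pytest.approx(0.5 * (1 + math.tanh(-12)), rel=1e-9)
        assert K.s0(0.0) < 1e-10

    def test_monotone(self):
        th = np.linspace(0, 1, 500)
        assert np.all(np.diff([K.s0(t) for t in th]) >= 0)


class TestRectification:
    def test_value_at_zero_mv(self, params):
        assert K.rectification_driving(0.0, params) == pytest.approx(-4.0)

    def test_value_at_minus80(self, params):
        assert K.rectification_driving(-80.0, params) == pytest.approx(
            -84.41, rel=1e-3)

    def test_zero_current_potential(self, params):
        root = brentq(lambda v: K.rectification_driving(v, params), 0.0, 40.0)
        assert root == pytest.approx(13.64, abs=0.01)

    def test_strictly_increasing_and_smooth_at_zero(self, params):
        v = np.linspace(-100, 60, 400)
        y = K.rectification_driving(v, params)
        assert np.all(np.diff(y) > 0)
        eps = 1e-9
        lo = K.rectification_driving(-eps, params)
        hi = K.rectification_driving(eps, params)
        assert abs(hi - lo) < 1e-6


class TestCurrent:
    def test_closed_channel(self, params):
        s = K.ChR2State()
        for v in (-80.0, 0.0, 40.0):
            assert K.chr2_current(s, v, params) == 0.0

    def test_gamma_sets_o2_conductance_ratio(self, params):
        i_o1 = K.chr2_current(K.ChR2State(o1=1.0), -60.0, params)
        i_o2 = K.chr2_current(K.ChR2State(o2=1.0), -60.0, params)
        assert i_o2 == pytest.approx(0.1 * i_o1, rel=1e-12)

    def test_zero_at_rectification_root(self, params):
        root = brentq(lambda v: K.rectification_driving(v, params), 0.0, 40.0)
        assert K.chr2_current(K.ChR2State(o1=0.5, o2=0.2), root,
                              params) == pytest.approx(0.0, abs=1e-10)

    def test_inward_below_crossing(self, params):
        assert K.chr2_current(K.ChR2State(o1=0.3), -80.0, params) < 0


class TestDerivatives:
    def test_dark_fixed_point(self, params):
        # occupancy derivatives vanish exactly; dp/dt only up to the
        # residual S0(0) ~ 6e-11 of the activation sigmoid
        d = K.derivatives(K.dark_steady_state(params), -80.0, 0.0, params)
        assert np.allclose(d[:3], 0.0, atol=1e-15)
        assert abs(d[3]) < 1e-9

    @given(st.floats(0, 0.4), st.floats(0, 0.3), st.floats(0, 0.3),
           st.floats(0, 1), st.floats(-100, 60), st.floats(0, 10))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_occupancy_conservation(self, o1, o2, c2, p, v, irr):
        """dC1/dt written out from the rate laws balances the integrated
        three occupancy derivatives: total probability flux is zero."""
        params = ChR2Params()
        d = K.derivatives(K.ChR2State(o1, o2, c2, p), v, irr, params)
        lr = K.light_rates(irr, p, params)
        vr = K.voltage_rates(v, params)
        c1 = 1.0 - o1 - o2 - c2
        dc1 = vr["gd1"] * o1 + vr["gr"] * c2 - lr["k1"] * c1
        assert abs(d[0] + d[1] + d[2] + dc1) < 1e-12

    def test_invalid_state_rejected(self, params):
        with pytest.raises(ValueError):
            K.derivatives(K.ChR2State(o1=0.8, o2=0.5), -80.0, 0.0, params)

    def test_nonfinite_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            K.derivatives(K.ChR2State(), math.nan, 0.0, params)


class TestDarkSteadyState:
    def test_sums_to_one(self, params):
        s = K.dark_steady_state(params)
        assert s.o1 + s.o2 + s.c2 + s.c1 == 1.0

    def test_c2_drains_in_dark(self, params):
        # Gr(-80) ~ 2.4e-4 ms^-1: 60 s covers ~14 recovery time constants
        light = LightProtocol([], 60000.0)
        t, Y = integrate_chr2(K.ChR2State(c2=0.5), light, lambda t: -80.0,
                              params, dt_out=100.0)
        assert Y[-1, 2] < 1e-3

    def test_p_relaxes_with_tau_chr2(self, params):
        light = LightProtocol([], 1.3)
        _, Y = integrate_chr2(K.ChR2State(p=1.0), light, lambda t: -80.0,
                              params, dt_out=1.3)
        assert Y[-1, 3] == pytest.approx(math.exp(-1.0), rel=1e-6)


def _rk4(y0, t_end, dt, v, irr, params):
    y = np.asarray(y0, float).copy()
    n = int(round(t_end / dt))
    f = K.derivatives_raw
    for _ in range(n):
        k1 = f(y, v, irr, params)
        k2 = f(y + 0.5 * dt * k1, v, irr, params)
        k3 = f(y + 0.5 * dt * k2, v, irr, params)
        k4 = f(y + dt * k3, v, irr, params)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def test_adaptive_solver_matches_fixed_step_oracle(params):
    """LSODA trajectory agrees with a 1 us fixed-step RK4 reference."""
    light = LightProtocol([(0.0, 50.0, 5.5)], 50.0)
    t, Y = integrate_chr2(K.dark_steady_state(params), light,
                          lambda t: -80.0, params, dt_out=10.0)
    y_ref = _rk4(np.zeros(4), 50.0, 1e-3, -80.0, 5.5, params)
    assert np.max(np.abs(Y[-1] - y_ref)) < 1e-5


def test_trajectory_stays_in_simplex(params):
    light = LightProtocol([(0.0, 500.0, 5.5)], 1000.0)
    _, Y = integrate_chr2(K.dark_steady_state(params), light,
                          lambda t: -80.0, params, dt_out=0.5)
    occ = np.column_stack([Y[:, 0], Y[:, 1], Y[:, 2],
                           1 - Y[:, :3].sum(axis=1)])
    assert occ.min() >= -1e-8
    assert occ.max() <= 1 + 1e-8
    assert np.max(np.abs(occ.sum(axis=1) - 1)) < 1e-8
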