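import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdsim.config import CellConfig
from emdsim.crossbridge import (
    CaSensitivity,
    CrossBridgeState,
    ForceLengthCurve,
    RateConstants,
    activation,
    ca50_of_length,
    calibrate_rates,
    force_length,
    gamma,
    heun_step,
    rest_state,
    steady_state_occupancies,
    xb_rhs,
)

CELL = CellConfig()
RC = RateConstants()


class TestCaSensitivity:
    def test_reference_length_gives_baseline(self):
        cs = CaSensitivity(ca50_0=0.7, b_ca=5.0)
        assert ca50_of_length(1.0, cs) == pytest.approx(0.7)

    def test_zero_exponent_is_length_independent(self):
        cs = CaSensitivity(ca50_0=0.7, b_ca=0.0)
        for l in (0.8, 1.0, 1.3):
            assert ca50_of_length(l, cs) == pytest.approx(0.7)

    def test_closed_form_value(self):
        cs = CaSensitivity(ca50_0=1.0, b_ca=8.3986)
        assert ca50_of_length(1.1, cs) == pytest.approx(0.43177, abs=1e-4)

    def test_strictly_decreasing_in_length(self):
        cs = CaSensitivity(ca50_0=1.0, b_ca=8.3986)
        ls = np.linspace(0.7, 1.4, 50)
        vals = ca50_of_length(ls, cs)
        assert np.all(np.diff(vals) < 0)


class TestForceLength:
    FLC = ForceLengthCurve()

    def test_plateau_is_one(self):
        assert force_length(1.0, self.FLC) == pytest.approx(1.0)

    def test_clamped_outside_support(self):
        assert force_length(0.3, self.FLC) == 0.0
        assert force_length(2.5, self.FLC) == 0.0

    def test_descending_limb_midpoint_is_mean_of_endpoints(self):
        (l1, f1), (l2, f2) = self.FLC.breakpoints[-2:]
        mid = 0.5 * (l1 + l2)
        assert force_length(mid, self.FLC) == pytest.approx(0.5 * (f1 + f2))


class TestRhs:
    def test_rest_with_zero_calcium_is_stationary(self):
        derivs = xb_rhs(rest_state(), 0.0, 1.0, 0.0, RC, CELL)
        assert all(d == 0.0 for d in derivs)

    @given(
        d=st.floats(0.0, 0.4),
        a1=st.floats(0.0, 0.3),
        a2=st.floats(0.0, 0.3),
        ca=st.floats(0.0, 10.0),
        l_hs=st.floats(0.7, 1.4),
    )
    @settings(max_examples=100, deadline=None)
    def test_occupancy_fluxes_balance(self, d, a1, a2, ca, l_hs):
        """Net flux out of the off state equals total occupancy change."""
        state = CrossBridgeState(d_frac=d, a1=a1, a2=a2, x1=0.0, x2=CELL.x0)
        dd, da1, da2, _, _ = xb_rhs(state, ca, l_hs, 0.0, RC, CELL)
        r_off = 1.0 - d - a1 - a2
        act = activation(ca, l_hs, RC, CaSensitivity())
        net_off_flux = RC.k_on * act * r_off - RC.k_off * d
        assert dd + da1 + da2 == pytest.approx(net_off_flux, abs=1e-12)

    def test_finite_derivatives_at_vanishing_occupancy(self):
        state = CrossBridgeState(d_frac=0.3, a1=0.0, a2=0.0, x1=0.1, x2=0.1)
        derivs = xb_rhs(state, 5.0, 1.0, 0.0, RC, CELL)
        assert all(np.all(np.isfinite(d)) for d in derivs)


class TestSteadyState:
    def test_matches_numerical_relaxation(self):
        d, a1, a2 = steady_state_occupancies(1.0, RC)
        st_ = rest_state()
        st_.x2 = CELL.x0
        dt = 0.05
        for _ in range(int(3000.0 / dt)):
            st_ = heun_step(st_, 100.0, 1.0, 0.0, dt, RC, CELL)
        assert st_.d_frac == pytest.approx(d, rel=1e-3)
        assert st_.a1 == pytest.approx(a1, rel=1e-3)
        assert st_.a2 == pytest.approx(a2, rel=1e-3)

    def test_tetanic_a2_reproduces_tabulated_normalization(self):
        """Saturating-calcium A2 must match A2max = 0.044456 within 10%."""
        _, _, a2 = steady_state_occupancies(1.0, RC)
        assert a2 == pytest.approx(CELL.a2max, rel=0.10)

    def test_steady_gamma_nondecreasing_in_calcium(self):
        cs = CaSensitivity()
        gammas = []
        for ca in (0.2, 0.5, 1.0, 2.0, 5.0):
            act = float(activation(ca, 1.0, RC, cs))
            _, a1, a2 = steady_state_occupancies(act, RC)
            state = CrossBridgeState(d_frac=0.0, a1=a1, a2=a2, x1=0.0,
                                     x2=CELL.x0)
            gammas.append(float(gamma(state, 1.0, CELL)))
        assert np.all(np.diff(gammas) >= 0)


class TestDistortionFixedPoint:
    def test_isometric_distortions_relax_to_power_stroke(self):
        """At sustained saturating calcium and zero sliding, x1 -> 0, x2 -> x0."""
        st_ = CrossBridgeState(d_frac=0.0, a1=0.0, a2=0.0, x1=0.004, x2=0.002)
        dt = 0.05
        for _ in range(int(2000.0 / dt)):
            st_ = heun_step(st_, 100.0, 1.0, 0.0, dt, RC, CELL)
        assert abs(st_.x1) < 1e-6 * CELL.x0
        assert st_.x2 == pytest.approx(CELL.x0, rel=1e-6)


class TestGamma:
    def test_rest_gamma_is_zero(self):
        assert gamma(rest_state(), 1.0, CELL) == 0.0

    def test_normalization_at_tetanic_reference(self):
        state = CrossBridgeState(d_frac=0.0, a1=0.0, a2=CELL.a2max, x1=0.0,
                                 x2=CELL.x0)
        assert gamma(state, 1.0, CELL) == pytest.approx(1.0)

    def test_descending_limb_scales_by_force_length(self):
        act = 1.0
        _, a1, a2 = steady_state_occupancies(act, RC)
        state = CrossBridgeState(d_frac=0.0, a1=a1, a2=a2, x1=0.0, x2=CELL.x0)
        l = 1.3  # descending limb
        expected = float(force_length(l)) * a2 / CELL.a2max
        assert gamma(state, l, CELL) == pytest.approx(expected)


class TestCalibrateRates:
    def test_rejects_unattainable_target(self):
        times = np.arange(0.0, 200.0, 0.1)
        v = np.where(times < 8.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            calibrate_rates(5.0, v, times, CELL)
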