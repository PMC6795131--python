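import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from emdsim.config import CellConfig, GeometryConfig, MaterialConfig
from emdsim.mechanics import (
    LAMBDA_OPT,
    OgdenMaterial,
    halfsarcomere_from_stretch,
    invert_nominal_stress,
    muscle_total_stress,
    ogden_strain_energy,
    ogden_uniaxial_nominal_stress,
    ogden_uniaxial_stiffness,
    solve_series_equilibrium,
)

MUSCLE = OgdenMaterial(mu=2.224, alpha=8.536)
TENDON = OgdenMaterial(mu=0.041, alpha=19.06)
CELL = CellConfig()
GEOM = GeometryConfig()
MATS = MaterialConfig()


class TestOgdenUniaxial:
    def test_reference_configuration_is_stress_free(self):
        assert ogden_uniaxial_nominal_stress(1.0, MUSCLE) == pytest.approx(0.0)
        assert ogden_uniaxial_nominal_stress(1.0, TENDON) == pytest.approx(0.0)

    def test_closed_form_values_at_large_stretch(self):
        assert ogden_uniaxial_nominal_stress(1.35, MUSCLE) == pytest.approx(
            20.89, abs=0.01
        )
        assert ogden_uniaxial_nominal_stress(1.35, TENDON) == pytest.approx(
            9.26, abs=0.01
        )

    def test_stress_is_derivative_of_strain_energy(self):
        h = 1e-6
        for mat in (MUSCLE, TENDON):
            for lam in np.linspace(0.75, 1.45, 15):
                fd = (
                    ogden_strain_energy(lam + h, mat)
                    - ogden_strain_energy(lam - h, mat)
                ) / (2 * h)
                p = ogden_uniaxial_nominal_stress(lam, mat)
                assert p == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_monotone_over_working_range(self):
        lams = np.linspace(0.7, 1.5, 200)
        for mat in (MUSCLE, TENDON):
            assert np.all(ogden_uniaxial_stiffness(lams, mat) > 0)
            assert np.all(np.diff(ogden_uniaxial_nominal_stress(lams, mat)) > 0)

    def test_incompressible_transverse_stretch(self):
        # J = lam * lam_t^2 = 1 with lam_t = lam^(-1/2), by construction
        lam = np.linspace(0.7, 1.5, 20)
        assert np.allclose(lam * (lam ** -0.5) ** 2, 1.0)

    @given(p=st.floats(-20.0, 60.0))
    @settings(max_examples=60, deadline=None)
    def test_inversion_round_trip(self, p):
        lam = invert_nominal_stress(p, MUSCLE)
        back = ogden_uniaxial_nominal_stress(lam, MUSCLE)
        assert back == pytest.approx(p, abs=1e-9 * max(1.0, abs(p)))


class TestMuscleTotalStress:
    def test_passive_limit(self):
        for lam in (0.9, 1.0, 1.2):
            assert muscle_total_stress(lam, 0.0, 0.0, MUSCLE, CELL) == (
                pytest.approx(float(ogden_uniaxial_nominal_stress(lam, MUSCLE)))
            )

    def test_full_activation_at_reference_gives_p_max(self):
        assert muscle_total_stress(1.0, 1.0, 0.0, MUSCLE, CELL) == (
            pytest.approx(CELL.p_max)
        )

    def test_superposition_is_linear_in_activation(self):
        a = muscle_total_stress(1.1, 0.3 + 0.2, 0.0, MUSCLE, CELL)
        b = muscle_total_stress(1.1, 0.3, 0.0, MUSCLE, CELL)
        assert a - b == pytest.approx(CELL.p_max * 0.2)


def _bisection_oracle(lambda_bar, gamma_uniform, geom, mats, cell):
    """Independent scalar solver: bisection on the common nominal stress."""

    def lam_of(p, mu, alpha, shift=0.0):
        return brentq(
            lambda x: mu * (x ** (alpha - 1) - x ** (-alpha / 2 - 1)) - (p - shift),
            1e-3, 10.0, xtol=1e-15,
        )

    def mismatch(p):
        lam_m = lam_of(p, mats.mu_m, mats.alpha_m,
                       shift=cell.p_max * gamma_uniform)
        lam_t = (lam_of(p, mats.mu_t, mats.alpha_t) if geom.mtr < 1 else 1.0)
        return geom.mtr * lam_m + (1 - geom.mtr) * lam_t - lambda_bar

    lo, hi = -50.0, 200.0
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        if mismatch(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSeriesEquilibrium:
    def test_no_tendon_passive_is_uniform(self):
        geom = GeometryConfig(mtr=1.0)
        eq = solve_series_equilibrium(1.2, np.zeros(10), 0.0, geom, MATS, CELL)
        assert np.allclose(eq.lambda_m, 1.2, atol=1e-10)
        assert eq.p_nominal == pytest.approx(
            float(ogden_uniaxial_nominal_stress(1.2, MUSCLE)), rel=1e-8
        )

    def test_homogeneous_rod_stretches_uniformly(self):
        mats = MaterialConfig(mu_m=0.5, alpha_m=12.0, mu_t=0.5, alpha_t=12.0)
        eq = solve_series_equilibrium(1.15, np.zeros(5), 0.0, GEOM, mats, CELL)
        assert np.allclose(eq.lambda_m, 1.15, atol=1e-8)
        assert eq.lambda_t == pytest.approx(1.15, abs=1e-8)

    @pytest.mark.parametrize("lambda_bar,gamma_u", [(1.25, 0.0), (1.05, 0.0),
                                                    (1.25, 0.1), (1.1, 0.3)])
    def test_matches_bisection_oracle(self, lambda_bar, gamma_u):
        eq = solve_series_equilibrium(
            lambda_bar, np.full(20, gamma_u), 0.0, GEOM, MATS, CELL, tol=1e-12
        )
        oracle = _bisection_oracle(lambda_bar, gamma_u, GEOM, MATS, CELL)
        assert eq.p_nominal == pytest.approx(oracle, abs=1e-8)

    def test_length_constraint_and_stress_continuity(self):
        gamma_field = np.linspace(0.0, 0.2, 20)  # non-uniform activation
        eq = solve_series_equilibrium(1.2, gamma_field, 0.0, GEOM, MATS, CELL,
                                      tol=1e-12)
        total = (GEOM.mtr * eq.lambda_m.mean()
                 + (1 - GEOM.mtr) * eq.lambda_t)
        assert total == pytest.approx(1.2, abs=1e-10)
        element_stress = muscle_total_stress(eq.lambda_m, gamma_field, 0.0,
                                             MUSCLE, CELL)
        assert np.allclose(element_stress, eq.p_nominal, atol=1e-8)

    def test_rejects_invalid_activation(self):
        with pytest.raises(ValueError):
            solve_series_equilibrium(1.2, np.array([0.1, np.nan]), 0.0, GEOM,
                                     MATS, CELL)


class TestHalfSarcomere:
    def test_optimum_maps_to_one(self):
        assert halfsarcomere_from_stretch(LAMBDA_OPT) == pytest.approx(1.0)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            halfsarcomere_from_stretch(0.0)
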