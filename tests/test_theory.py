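"""Closed-form values, limits, continuity and analytic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from beauwalk import (
    MacroParams,
    ModelParams,
    TaxisSpec,
    convection_speed,
    furth_msd,
    gaussian_density,
    macro_params,
    motility_coefficient,
    msd_ensemble,
    msd_linear_coeffs,
    msd_single,
    normalized_sq_confinement,
    sq_confinement,
)

params_strategy = st.builds(
    ModelParams,
    t_pause=st.floats(0.0, 10.0),
    t_free=st.floats(0.1, 10.0),
    v_free=st.floats(0.1, 50.0),
)


class TestMotilityCoefficient:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((0.5, 2.0, 18.8), 94.25),
            ((0.5, 2.5, 16.6), 95.68),
            ((0.25, 2.0, 17.6), 91.78),
            ((0.75, 1.5, 23.8), 94.41),
            ((9.32, 2.0, 40.0), 94.23),  # M-degenerate partner of the best fit
        ],
    )
    def test_published_triplets(self, triplet, expected):
        assert round(motility_coefficient(ModelParams(*triplet)), 2) == expected

    def test_ideal_chain_limit(self):
        # Zero pause reduces the model to a freely jointed chain:
        # M = v^2 t_free / 6.
        p = ModelParams(0.0, 3.0, 10.0)
        assert motility_coefficient(p) == pytest.approx(10.0**2 * 3.0 / 6.0)


class TestSingleCellMsd:
    def test_flat_during_pause(self, best_fit):
        for tau in [0.0, 0.25, best_fit.t_pause]:
            assert msd_single(best_fit.t_run, tau, best_fit) == pytest.approx(
                2 * motility_coefficient(best_fit) * best_fit.t_run
            )

    def test_end_of_first_cycle(self, best_fit):
        # Continuity with the next cycle: the pulse tops out at 2 M t_run.
        val = msd_single(0.0, best_fit.t_run - 1e-9, best_fit)
        assert val == pytest.approx(471.25, rel=1e-4)

    def test_mid_run_quadratic_growth(self, best_fit):
        val = msd_single(0.0, best_fit.t_pause + 1.0, best_fit)
        assert val == pytest.approx(18.8**2 / 3.0, rel=1e-12)
        assert val == pytest.approx(117.81, rel=1e-3)

    def test_dims_scaling(self, best_fit):
        one = msd_single(best_fit.t_run, 0.1, best_fit, dims=1)
        assert msd_single(best_fit.t_run, 0.1, best_fit, dims=3) == pytest.approx(3 * one)

    def test_rejects_non_cycle_times(self, best_fit):
        with pytest.raises(ValueError):
            msd_single(1.0, 0.0, best_fit)
        with pytest.raises(ValueError):
            msd_single(best_fit.t_run, best_fit.t_run, best_fit)


class TestEnsembleMsd:
    def test_reference_values(self, best_fit):
        assert msd_ensemble(0.0, best_fit) == 0.0
        assert msd_ensemble(60.0, best_fit) == pytest.approx(11184.33, rel=1e-4)
        assert msd_ensemble(1.0, best_fit) == pytest.approx(78.54, rel=1e-3)

    def test_linear_regime_is_exact_line(self, best_fit):
        alpha, beta = msd_linear_coeffs(best_fit)
        assert alpha == pytest.approx(188.5, rel=1e-4)
        assert beta == pytest.approx(-125.67, rel=1e-4)
        t = np.linspace(best_fit.t_free, 100.0, 50)
        np.testing.assert_allclose(msd_ensemble(t, best_fit), alpha * t + beta, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=params_strategy)
    def test_branch_continuity_and_smooth_start(self, params):
        tf = params.t_free
        below = msd_ensemble(tf * (1 - 1e-10), params)
        above = msd_ensemble(tf * (1 + 1e-10), params)
        assert above == pytest.approx(below, rel=1e-6, abs=1e-9)
        # zero value and zero slope at t = 0 (cubic branch)
        eps = 1e-7 * tf
        assert msd_ensemble(0.0, params) == 0.0
        assert msd_ensemble(eps, params) / max(eps, 1e-300) < 1e-4 * max(
            1.0, motility_coefficient(params)
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=params_strategy)
    def test_intercept_slope_ratio_identity(self, params):
        alpha, beta = msd_linear_coeffs(params)
        assert beta / alpha == pytest.approx(-params.t_free / 3.0, rel=1e-12)

    def test_two_degrees_of_freedom(self, best_fit):
        # Doubling t_pause while rescaling v_free to hold M (at fixed t_free)
        # leaves the entire population MSD unchanged.
        scale = np.sqrt((best_fit.t_free + 2 * best_fit.t_pause) / best_fit.t_run)
        twin = ModelParams(2 * best_fit.t_pause, best_fit.t_free, best_fit.v_free * scale)
        assert motility_coefficient(twin) == pytest.approx(motility_coefficient(best_fit))
        assert msd_linear_coeffs(twin) == pytest.approx(msd_linear_coeffs(best_fit))

    def test_ideal_chain_values_at_cycle_multiples(self):
        # t_pause = 0: at t = k t_free the MSD equals k (v t_free)^2 / 3
        # minus the constant ensemble offset... the freely jointed chain
        # prediction applies to the synchronized walk:
        params = ModelParams(0.0, 2.0, 10.0)
        for k in [1, 3, 7]:
            assert msd_single(k * params.t_free, 0.0, params) == pytest.approx(
                k * params.step_radius**2 / 3.0
            )


class TestConfinement:
    def test_limits_and_branch_point(self):
        params = ModelParams(0.0, 2.0, 18.8)
        assert sq_confinement(0.0, params) == pytest.approx(1.0 / 3.0)
        assert sq_confinement(params.t_free, params) == pytest.approx(2.0 / 9.0)
        assert sq_confinement(1e7, params) < 1e-5

    def test_closed_form_both_branches(self):
        # (3 max(t, tf) - min(t, tf)) tf / (3 max(t, tf))^2
        params = ModelParams(0.0, 2.0, 18.8)
        tf = params.t_free
        for t in [0.3, 1.0, 1.9, 2.0, 3.7, 25.0]:
            hi, lo = max(t, tf), min(t, tf)
            assert sq_confinement(t, params) == pytest.approx(
                (3 * hi - lo) * tf / (3 * hi) ** 2, rel=1e-12
            )

    def test_monotone_non_increasing(self):
        params = ModelParams(0.0, 1.5, 10.0)
        t = np.linspace(0.0, 50.0, 400)
        vals = sq_confinement(t, params)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_requires_zero_pause_unless_overridden(self, best_fit):
        with pytest.raises(ValueError):
            sq_confinement(1.0, best_fit)
        val = sq_confinement(1.0, best_fit, allow_pause=True)
        assert np.isfinite(val) and val > 0

    def test_normalized_converges_to_third_of_persistence_time(self):
        params = ModelParams(0.0, 2.0, 18.8)
        assert normalized_sq_confinement(1e8, params) == pytest.approx(2.0 / 3.0, rel=1e-6)
        assert normalized_sq_confinement(params.t_free, params) == pytest.approx(
            params.t_free * 2.0 / 9.0
        )
        t = np.linspace(params.t_free, 500.0, 300)
        assert np.all(np.diff(normalized_sq_confinement(t, params)) > 0)


class TestConvectionSpeed:
    def test_unbiased_limits(self, best_fit):
        for mode in ["none", "simple", "orthotaxis", "topotaxis", "klinotaxis"]:
            assert convection_speed(mode, 0.0, best_fit) == 0.0

    def test_semi_mechanistic_modes_share_one_speed(self, best_fit):
        ortho = convection_speed("orthotaxis", 0.6, best_fit)
        assert ortho == pytest.approx(0.6 * 18.8 * 2.0 / (3 * 2.5))
        assert convection_speed("topotaxis", 0.6, best_fit) == ortho
        assert convection_speed("klinotaxis", 0.6, best_fit) == ortho

    def test_simple_mode_speed(self, best_fit):
        assert convection_speed("simple", 1.0, best_fit) == pytest.approx(3.76)

    def test_unknown_mode_rejected(self, best_fit):
        with pytest.raises(ValueError):
            convection_speed("phototaxis", 0.5, best_fit)

    def test_macro_params_bundle(self, best_fit):
        mp = macro_params(best_fit, TaxisSpec("orthotaxis", 1.0, [0, 1, 0]))
        assert isinstance(mp, MacroParams)
        assert mp.M == pytest.approx(94.2507, rel=1e-4)
        assert np.allclose(mp.C, [0.0, 5.0133, 0.0], atol=1e-3)


class TestFurth:
    def test_origin_and_memoryless_limit(self):
        assert furth_msd(0.0, 94.25, 1.0) == 0.0
        t = np.array([1.0, 5.0, 20.0])
        np.testing.assert_allclose(furth_msd(t, 94.25, 0.0), 2 * 94.25 * t)
        np.testing.assert_allclose(furth_msd(t, 94.25, 1e-9), 2 * 94.25 * t, rtol=1e-6)

    def test_value_at_persistence_time(self):
        M, P = 94.25, 3.0
        assert furth_msd(P, M, P) == pytest.approx(2 * M * P * np.exp(-1.0))


class TestGaussianDensity:
    def test_normalization_and_moments(self):
        C, M, t = 2.0, 94.25, 10.0
        total, _ = quad(lambda x: gaussian_density(x, t, C, M), -np.inf, np.inf)
        assert total == pytest.approx(1.0, rel=1e-8)
        mean, _ = quad(lambda x: x * gaussian_density(x, t, C, M), -np.inf, np.inf)
        assert mean == pytest.approx(C * t, rel=1e-8)
        var, _ = quad(lambda x: (x - C * t) ** 2 * gaussian_density(x, t, C, M), -np.inf, np.inf)
        assert var == pytest.approx(2 * M * t, rel=1e-6)

    def test_solves_convection_diffusion_equation(self):
        # Central finite differences of phi_t + C phi_x - M phi_xx ~ 0.
        C, M, t = 1.5, 50.0, 8.0
        x = np.linspace(-150, 250, 2001)
        dx = x[1] - x[0]
        dt = 1e-4
        phi = gaussian_density(x, t, C, M)
        phi_t = (gaussian_density(x, t + dt, C, M) - gaussian_density(x, t - dt, C, M)) / (2 * dt)
        phi_x = np.gradient(phi, dx)
        phi_xx = np.gradient(phi_x, dx)
        resid = phi_t + C * phi_x - M * phi_xx
        assert np.max(np.abs(resid[5:-5])) < 1e-3 * np.max(np.abs(phi_t))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gaussian_density(0.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gaussian_density(0.0, 1.0, 1.0, 0.0)
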