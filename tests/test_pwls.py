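"""PWLS regression: weights, moving average, fits, oracle equivalence."""

import io

import numpy as np
import pytest
from scipy import optimize

from reflexgait.modulator import PolynomialModel
from reflexgait.pwls import (
    GaitDataset,
    GaitRecord,
    SingularFitError,
    WeightConfig,
    compute_weights,
    fit_modulator,
    fit_pwls,
    moving_average_cot,
    performance_weights,
)
from reflexgait.registry import DEFAULTS, N_PARAMS, ParameterVector
from reflexgait.surrogate import make_two_level_dataset, make_polynomial_dataset


def toy_dataset(cots, velocities=None):
    n = len(cots)
    v = np.arange(1, n + 1, dtype=float) if velocities is None else np.asarray(velocities)
    return GaitDataset(
        v_x=v, cot=np.asarray(cots, dtype=float), Y=np.tile(DEFAULTS, (n, 1))
    )


def pwls_error(v, y, beta, omega):
    """E_PWLS = ||beta (.) (y - V w)||^2, direct definition."""
    V = np.vander(v, len(omega), increasing=True)
    r = beta * (y - V @ omega)
    return float(r @ r)


class TestMovingAverage:
    def test_constant_series(self):
        ds = toy_dataset([0.4] * 7)
        assert all(moving_average_cot(ds, j, 2) == pytest.approx(0.4) for j in range(7))

    def test_interior_window(self):
        ds = toy_dataset([1, 2, 3, 4, 5])
        assert moving_average_cot(ds, 2, 1) == pytest.approx(3.0)

    def test_edge_window_shrinks(self):
        ds = toy_dataset([1, 2, 3, 4, 5])
        assert moving_average_cot(ds, 0, 1) == pytest.approx(1.5)
        assert moving_average_cot(ds, 4, 1) == pytest.approx(4.5)

    def test_full_window_width_is_2M_plus_1(self):
        M = 125
        ds = toy_dataset(np.linspace(0.3, 0.9, 600))
        j = 300
        assert moving_average_cot(ds, j, M) == pytest.approx(
            ds.cot[j - M : j + M + 1].mean()
        )

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            moving_average_cot(toy_dataset([1.0]), 3, 1)


class TestPerformanceWeights:
    def test_at_local_mean_weight_is_one(self):
        assert performance_weights(0.5, 0.5, 1e6) == pytest.approx(1.0)

    def test_A_equal_one_is_uniform(self):
        assert performance_weights(0.123, 0.5, 1.0) == pytest.approx(1.0)

    def test_printed_substitution(self):
        assert performance_weights(0.45, 0.5, 100.0) == pytest.approx(100**0.1, rel=1e-12)

    def test_better_than_mean_iff_weight_above_one(self):
        assert performance_weights(0.4, 0.5, 10.0) > 1.0
        assert performance_weights(0.6, 0.5, 10.0) < 1.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            performance_weights(0.5, 0.0, 10.0)
        with pytest.raises(ValueError):
            performance_weights(0.5, 0.5, 0.5)

    def test_extreme_A_no_overflow_in_pipeline(self):
        ds = toy_dataset(np.concatenate([[0.1] * 5, [5.0] * 5]))
        beta = compute_weights(ds, WeightConfig(A=1e300, M_window=9))
        assert np.all(np.isfinite(beta))
        assert beta.max() == pytest.approx(1.0)


class TestFitPwls:
    def test_interpolation_independent_of_weights(self):
        v = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 5.0])
        for beta in (np.ones(3), np.array([10.0, 0.1, 3.0])):
            model = fit_pwls(v, y, beta, 2)
            np.testing.assert_allclose(model.omega, [1.0, 0.0, 1.0], atol=1e-9)

    def test_uniform_weights_equal_ols(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.4, 2.0, 30)
        y = np.sin(v) + 0.1 * rng.standard_normal(30)
        m_ols = fit_pwls(v, y, np.ones(30), 4)
        m_c = fit_pwls(v, y, np.full(30, 7.3), 4)
        np.testing.assert_allclose(m_ols.omega, m_c.omega, rtol=1e-9, atol=1e-12)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.4, 2.0, 40)
        y = rng.standard_normal(40)
        beta = rng.uniform(0.1, 5.0, 40)
        a = fit_pwls(v, y, beta, 5)
        b = fit_pwls(v, y, 123.4 * beta, 5)
        np.testing.assert_allclose(a.omega, b.omega, rtol=1e-9, atol=1e-12)

    def test_matches_statsmodels_wls(self):
        """Independent route: WLS with weights beta^2 solves the same problem."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        v = rng.uniform(0.4, 2.0, 50)
        y = np.cos(2 * v) + 0.05 * rng.standard_normal(50)
        beta = rng.uniform(0.2, 4.0, 50)
        ours = fit_pwls(v, y, beta, 4)
        V = np.vander(v, 5, increasing=True)
        ref = sm.WLS(y, V, weights=beta**2).fit().params
        np.testing.assert_allclose(ours.omega, ref, rtol=1e-7, atol=1e-9)

    def test_matches_brute_force_minimizer(self):
        """Fitted values agree with direct numerical minimization of E_PWLS."""
        rng = np.random.default_rng(3)
        v = rng.uniform(0.4, 2.0, 40)
        y = np.sin(3 * v) + 0.1 * rng.standard_normal(40)
        beta = rng.uniform(0.1, 10.0, 40)
        m = 4
        ours = fit_pwls(v, y, beta, m)

        center, scale = v.mean(), v.std()
        Vs = np.vander((v - center) / scale, m + 1, increasing=True)

        def E(c):
            r = beta * (y - Vs @ c)
            return r @ r

        res = optimize.minimize(E, np.zeros(m + 1), method="BFGS", tol=1e-14)
        fitted_oracle = Vs @ res.x
        np.testing.assert_allclose(ours(v), fitted_oracle, atol=1e-6)

    def test_optimality_beats_ols_on_weighted_error(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.4, 2.0, 35)
        y = rng.standard_normal(35)
        beta = rng.uniform(0.1, 8.0, 35)
        ours = fit_pwls(v, y, beta, 3)
        ols = fit_pwls(v, y, np.ones(35), 3)
        assert pwls_error(v, y, beta, ours.omega) <= pwls_error(v, y, beta, ols.omega) + 1e-9

    def test_normal_equations_identity(self):
        """The QR route solves exactly the explicit normal-equations problem."""
        rng = np.random.default_rng(5)
        v = rng.uniform(0.5, 1.8, 25)
        y = rng.standard_normal(25)
        beta = rng.uniform(0.5, 2.0, 25)
        m = 3
        ours = fit_pwls(v, y, beta, m)
        V = np.vander(v, m + 1, increasing=True)
        BV = beta[:, None] * V
        ref = np.linalg.solve(BV.T @ BV, BV.T @ (beta * y))
        np.testing.assert_allclose(ours.omega, ref, rtol=1e-6, atol=1e-9)

    def test_rank_deficiency_raises(self):
        v = np.array([1.0, 1.0, 1.0, 2.0])
        with pytest.raises(SingularFitError):
            fit_pwls(v, np.ones(4), np.ones(4), 3)

    def test_too_few_points_raises(self):
        with pytest.raises(SingularFitError):
            fit_pwls(np.array([1.0, 2.0]), np.ones(2), np.ones(2), 3)


class TestPolynomialModel:
    def test_evaluation(self):
        assert PolynomialModel(2, np.array([1.0, 0.0, 1.0]))(2.0) == pytest.approx(5.0)

    def test_degree_zero_constant(self):
        m = PolynomialModel(0, np.array([3.5]))
        assert m(0.1) == m(100.0) == 3.5

    def test_horner_equals_power_sum(self):
        rng = np.random.default_rng(6)
        omega = rng.standard_normal(7)
        model = PolynomialModel(6, omega)
        v = rng.uniform(0.4, 2.0, 20)
        naive = sum(w * v**j for j, w in enumerate(omega))
        np.testing.assert_allclose(model(v), naive, rtol=1e-12, atol=1e-12)


class TestFitModulator:
    def test_A1_equals_ols_per_parameter(self, two_level_dataset):
        mod_a1 = fit_modulator(two_level_dataset, m=6, config=WeightConfig(A=1.0))
        beta1 = np.ones(len(two_level_dataset))
        for name in ("G_HFL", "theta_t_tar"):
            direct = fit_pwls(
                two_level_dataset.v_x, two_level_dataset.parameter_series(name), beta1, 6
            )
            np.testing.assert_allclose(
                mod_a1.polynomials[name].omega, direct.omega, rtol=1e-9, atol=1e-10
            )

    def test_bias_pulls_fit_toward_efficient_subset(self, two_level_dataset):
        eff = np.isclose(two_level_dataset.cot, 0.5)
        v_eff = two_level_dataset.v_x[eff]
        y_eff = two_level_dataset.parameter_series("G_HFL")[eff]
        residuals = []
        for A in (1.0, 1e2, 1e6):
            mod = fit_modulator(two_level_dataset, m=6, config=WeightConfig(A=A))
            pred = mod.polynomials["G_HFL"](v_eff)
            residuals.append(float(np.mean((pred - y_eff) ** 2)))
        assert residuals[0] > residuals[-1]
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_polynomial_truth_recovered_for_any_A(self):
        ds, coeffs = make_polynomial_dataset(np.linspace(0.4, 2.0, 40), seed=5)
        for A in (1.0, 1e6):
            mod = fit_modulator(ds, m=6, config=WeightConfig(A=A, M_window=10))
            for name, omega in coeffs.items():
                np.testing.assert_allclose(
                    mod.polynomials[name].omega, omega, atol=1e-6
                )

    def test_metadata_recorded(self, two_level_dataset):
        mod = fit_modulator(two_level_dataset, m=6, config=WeightConfig(A=100.0, M_window=7))
        assert mod.A == 100.0
        assert mod.M_window == 7
        assert mod.degree == 6
        assert mod.velocity_range == (
            pytest.approx(two_level_dataset.v_x.min()),
            pytest.approx(two_level_dataset.v_x.max()),
        )

    def test_too_small_dataset_raises(self):
        ds = toy_dataset([0.5] * 5)
        with pytest.raises(SingularFitError):
            fit_modulator(ds, m=6)


class TestGaitDataset:
    def test_sorted_ascending_with_stable_ties(self):
        Y = np.tile(DEFAULTS, (4, 1))
        Y[:, 0] = [10, 20, 30, 40]
        ds = GaitDataset(v_x=np.array([1.2, 0.8, 1.2, 0.5]), cot=np.ones(4) * 0.4, Y=Y)
        assert list(ds.v_x) == [0.5, 0.8, 1.2, 1.2]
        # stable: the first 1.2 record (marker 10) precedes the second (30)
        assert list(ds.Y[2:, 0]) == [10, 30]

    def test_records_validate(self):
        with pytest.raises(ValueError):
            GaitRecord(v_x=-1.0, Y=ParameterVector.defaults(), cot=0.4)
        with pytest.raises(ValueError):
            GaitRecord(v_x=1.0, Y=ParameterVector.defaults(), cot=0.0)

    def test_csv_round_trip(self, two_level_dataset):
        buf = io.StringIO()
        two_level_dataset.to_csv(buf)
        buf.seek(0)
        back = GaitDataset.from_csv(buf)
        np.testing.assert_allclose(back.v_x, two_level_dataset.v_x)
        np.testing.assert_allclose(back.cot, two_level_dataset.cot)
        np.testing.assert_allclose(back.Y, two_level_dataset.Y)

    def test_csv_header_mismatch_rejected(self):
        buf = io.StringIO("a,b\n1,2\n")
        with pytest.raises(ValueError):
            GaitDataset.from_csv(buf)
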