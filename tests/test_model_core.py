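"""Partial likelihood, score and information against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from gamar.model_core import (
    Dataset,
    ModelSpec,
    ParameterVector,
    PredictorOverflowError,
    SmoothTerm,
    build_design,
    clip_counts,
    dispersion,
    information,
    linear_predictor,
    log_partial_likelihood,
    pearson_residuals,
    score,
)

from conftest import make_small_fixture


class TestClipCounts:
    def test_zeros_raised_to_tau(self):
        assert clip_counts([0, 1, 5], 0.5).tolist() == [0.5, 1.0, 5.0]

    def test_positive_counts_unchanged(self):
        y = np.array([1, 2, 9])
        assert np.array_equal(clip_counts(y, 1.0), y.astype(float))

    def test_all_zero(self):
        assert clip_counts([0, 0], 0.25).tolist() == [0.25, 0.25]

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            clip_counts([1, 2], 0.0)


class TestLinearPredictor:
    def test_p0_is_plain_gam(self):
        design, theta, y, ystar = make_small_fixture(0, p=0)
        eta = linear_predictor(theta, design, ystar)
        assert np.allclose(eta, design.X @ theta.beta)

    def test_zero_ar_coefficients_match_p0(self):
        design, theta, y, ystar = make_small_fixture(1, p=2)
        theta0 = ParameterVector(theta.beta, np.zeros(2))
        eta = linear_predictor(theta0, design, ystar)
        assert np.allclose(eta, (design.X @ theta.beta)[2:])

    def test_hand_computed_ar1_value(self):
        # intercept-only, beta=1, c1=0.5, ln y*_1 = 2 -> eta_2 = 1 + 0.5(2-1)
        from gamar.model_core import DesignInfo

        design = DesignInfo(
            X=np.ones((2, 1)),
            column_names=["(intercept)"],
            column_map={"(intercept)": [0]},
            spline_specs={},
            offset=0,
        )
        theta = ParameterVector(np.array([1.0]), np.array([0.5]))
        eta = linear_predictor(theta, design, np.array([np.exp(2.0), 1.0]))
        assert eta == pytest.approx([1.5])

    def test_overflow_guard_names_position(self):
        design, theta, y, ystar = make_small_fixture(2, p=1)
        bad = ParameterVector(theta.beta + 100.0, theta.c)
        with pytest.raises(PredictorOverflowError, match="position"):
            linear_predictor(bad, design, ystar)


class TestLogPartialLikelihood:
    @pytest.mark.parametrize("y0,expected", [(0.0, -1.0), (1.0, -1.0)])
    def test_single_point_mu_one(self, y0, expected):
        from gamar.model_core import DesignInfo

        design = DesignInfo(
            X=np.zeros((1, 1)),
            column_names=["(intercept)"],
            column_map={"(intercept)": [0]},
            spline_specs={},
            offset=0,
        )
        theta = ParameterVector(np.array([0.0]))  # mu = 1
        ll = log_partial_likelihood(theta, design, np.array([y0]), np.array([max(y0, 0.5)]))
        assert ll == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_poisson_pmf_oracle(self, seed):
        design, theta, y, ystar = make_small_fixture(seed, p=2)
        eta = linear_predictor(theta, design, ystar)
        mu = np.exp(eta)
        oracle = stats.poisson.logpmf(y[2:].astype(int), mu).sum()
        ll = log_partial_likelihood(theta, design, y, ystar)
        assert ll == pytest.approx(oracle, rel=1e-10)


class TestScoreAndInformation:
    @pytest.mark.parametrize("seed,m,p", [(10, 3, 2), (11, 4, 3), (12, 2, 1), (13, 4, 0)])
    def test_score_matches_finite_differences(self, seed, m, p):
        design, theta, y, ystar = make_small_fixture(seed, m=m, p=p)

        def f(th):
            return log_partial_likelihood(
                ParameterVector.from_full(th, m), design, y, ystar
            )

        num = approx_fprime(theta.full, f, 1e-7)
        ana = score(theta, design, y, ystar)
        assert np.allclose(ana, num, rtol=1e-5, atol=1e-4 * max(1, np.abs(num).max()))

    @pytest.mark.parametrize("seed,m,p", [(20, 3, 2), (21, 4, 3), (22, 2, 1)])
    def test_information_matches_numerical_hessian(self, seed, m, p):
        design, theta, y, ystar = make_small_fixture(seed, m=m, p=p)

        def g(th):
            return score(ParameterVector.from_full(th, m), design, y, ystar)

        k = m + p
        h = 1e-6
        H = np.empty((k, k))
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            H[:, j] = (g(theta.full + e) - g(theta.full - e)) / (2 * h)
        gamma = information(theta, design, y, ystar)
        assert np.allclose(gamma, -H, rtol=1e-4, atol=1e-4 * np.abs(H).max())

    def test_information_symmetric(self):
        design, theta, y, ystar = make_small_fixture(23, m=4, p=3)
        gamma = information(theta, design, y, ystar)
        assert np.array_equal(gamma, gamma.T)

    def test_p0_reduces_to_poisson_glm(self):
        design, theta, y, ystar = make_small_fixture(24, m=4, p=0)
        mu = np.exp(design.X @ theta.beta)
        assert np.allclose(score(theta, design, y, ystar), design.X.T @ (y - mu))
        assert np.allclose(
            information(theta, design, y, ystar),
            (design.X * mu[:, None]).T @ design.X,
        )

    def test_score_zero_at_saturating_theta(self):
        # intercept-only model with constant y: mu = y at beta = ln y
        from gamar.model_core import DesignInfo

        design = DesignInfo(
            X=np.ones((10, 1)),
            column_names=["(intercept)"],
            column_map={"(intercept)": [0]},
            spline_specs={},
            offset=0,
        )
        y = np.full(10, 7.0)
        theta = ParameterVector(np.array([np.log(7.0)]))
        assert np.allclose(score(theta, design, y, np.maximum(y, 0.5)), 0.0)


class TestShiftCovariance:
    def test_constant_shift_absorbed_by_intercept(self):
        design, theta, y, ystar = make_small_fixture(30, m=3, p=2)
        kappa = 2.7
        X2 = design.X.copy()
        X2[:, 1] += kappa
        from gamar.model_core import DesignInfo

        design2 = DesignInfo(
            X=X2,
            column_names=design.column_names,
            column_map=design.column_map,
            spline_specs={},
            offset=0,
        )
        beta2 = theta.beta.copy()
        beta2[0] -= kappa * theta.beta[1]
        theta2 = ParameterVector(beta2, theta.c)
        assert np.allclose(
            linear_predictor(theta, design, ystar),
            linear_predictor(theta2, design2, ystar),
        )
        assert log_partial_likelihood(theta, design, y, ystar) == pytest.approx(
            log_partial_likelihood(theta2, design2, y, ystar)
        )


class TestResidualsAndDispersion:
    def test_pearson_values(self):
        z = pearson_residuals(np.array([1.0, 4.0, 2.0]), np.array([4.0, 0.0, 2.0]))
        assert z == pytest.approx([3.0, -2.0, 0.0])

    def test_pearson_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            pearson_residuals(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_dispersion_mean_square(self):
        assert dispersion(np.array([1.0, -1.0, 1.0, -1.0]), 0) == pytest.approx(1.0)
        assert dispersion(np.zeros(5), 1) == 0.0
        with pytest.raises(ValueError):
            dispersion(np.ones(3), 3)


class TestDatasetAndDesign:
    def test_dataset_validates_contiguity_and_counts(self):
        import pandas as pd

        frame = pd.DataFrame({"y": [1, 2, 3]}, index=[1, 2, 4])
        with pytest.raises(ValueError, match="gap"):
            Dataset(frame=frame)
        frame = pd.DataFrame({"y": [1, -2, 3]}, index=[1, 2, 3])
        with pytest.raises(ValueError, match="nonnegative"):
            Dataset(frame=frame)

    def test_lagged_smooth_drops_presample_rows(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 60
        frame = pd.DataFrame(
            {"y": rng.poisson(5.0, n), "temp": rng.normal(size=n)},
            index=pd.RangeIndex(1, n + 1),
        )
        data = Dataset(frame=frame)
        spec = ModelSpec([SmoothTerm("temp", 3, lag=4)], ar_order=0)
        design = build_design(spec, data)
        assert design.offset == 4
        assert design.X.shape == (n - 4, 4)
        # lagged column block evaluates the basis at temp shifted by 4 days
        from gamar.splines import evaluate_basis

        sspec = design.spline_specs[spec.terms[0].label()]
        expect = evaluate_basis(sspec, frame["temp"].to_numpy()[: n - 4]).values
        assert np.allclose(design.X[:, 1:], expect)

    def test_factor_term_indicator_columns(self):
        import pandas as pd

        n = 21
        week = np.tile(np.arange(7), 3)
        frame = pd.DataFrame(
            {"y": np.ones(n, dtype=int), "week": week},
            index=pd.RangeIndex(1, n + 1),
        )
        from gamar.model_core import FactorTerm

        data = Dataset(frame=frame)
        design = build_design(ModelSpec([FactorTerm("week")], ar_order=0), data)
        assert design.X.shape == (n, 7)  # intercept + 6 indicators
        assert np.allclose(design.X[:, 1:].sum(axis=1) + (week == 0), 1.0)
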