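import math

import numpy as np
import pytest
from scipy import stats

from gtridge import (
    alpha_of_lambda,
    conic_classify,
    detectable_cov,
    f_statistic,
    make_beta,
    select_lambda_ft,
    select_lambda_gt,
    svd_decompose,
)


class TestAlphaOfLambda:
    def test_infinite_penalty_is_global_null(self, signal_data):
        X, y, _ = signal_data
        from gtridge import gt_test_linear

        assert alpha_of_lambda(X, y, math.inf) == pytest.approx(
            gt_test_linear(X, y).pvalue, abs=1e-9
        )

    def test_zero_penalty_saturates(self, signal_data):
        X, y, _ = signal_data
        assert alpha_of_lambda(X, y, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_nonincreasing_profile(self, signal_data):
        X, y, _ = signal_data
        grid = np.logspace(-2, 4, 50)
        vals = [alpha_of_lambda(X, y, lam) for lam in grid]
        assert all(a >= b - 1e-7 for a, b in zip(vals, vals[1:]))


class TestSelectLambdaGT:
    def test_null_data_frequency(self, small_design):
        # under the global null the infinite penalty is chosen with
        # probability 1 - alpha (exact pivot)
        X, _ = small_design
        alpha, reps = 0.5, 200
        hits = 0
        for rep in range(reps):
            y = np.random.default_rng(1000 + rep).standard_normal(50)
            hits += math.isinf(select_lambda_gt(X, y, alpha).lam)
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert hits / reps == pytest.approx(1 - alpha, abs=3 * se)

    def test_monotone_in_alpha(self, signal_data):
        X, y, _ = signal_data
        lams = [select_lambda_gt(X, y, a).lam for a in (0.05, 0.2, 0.5, 0.8)]
        assert all(a >= b for a, b in zip(lams, lams[1:]))

    def test_matches_dense_grid(self, signal_data):
        X, y, _ = signal_data
        alpha = 0.3
        res = select_lambda_gt(X, y, alpha)
        assert math.isfinite(res.lam)
        center = math.log10(res.lam)
        dense = np.logspace(center - 2, center + 2, 2000)
        inside = [lam for lam in dense if alpha_of_lambda(X, y, lam) >= alpha]
        oracle = max(inside)
        # agree within dense-grid resolution
        assert abs(center - math.log10(oracle)) < 2 * (4 / 2000)

    def test_self_consistency_at_boundary(self, signal_data):
        X, y, _ = signal_data
        res = select_lambda_gt(X, y, 0.3)
        assert alpha_of_lambda(X, y, res.lam) >= 0.3
        assert alpha_of_lambda(X, y, res.lam * 1.01) < 0.3

    def test_sentinel_iff_null_accepted(self, small_design):
        X, _ = small_design
        y = np.random.default_rng(3).standard_normal(50)
        for alpha in (0.05, 0.5, 0.9):
            res = select_lambda_gt(X, y, alpha)
            assert math.isinf(res.lam) == (res.pvalue_null >= alpha)

    def test_duality_round_trip(self, signal_data):
        X, y, _ = signal_data
        lam0 = 5.0
        a0 = alpha_of_lambda(X, y, lam0)
        res = select_lambda_gt(X, y, a0)
        # selecting at the implied level recovers a penalty >= lam0
        assert res.lam >= lam0 * (1 - 1e-3)

    def test_invalid_alpha(self, signal_data):
        X, y, _ = signal_data
        with pytest.raises(ValueError):
            select_lambda_gt(X, y, 1.5)


class TestSelectLambdaFT:
    def test_center_always_inside(self, signal_data):
        X, y, _ = signal_data
        assert f_statistic(X, y, np.linalg.lstsq(X, y, rcond=None)[0]) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_null_data_frequency(self, small_design):
        X, _ = small_design
        alpha, reps = 0.5, 200
        hits = 0
        for rep in range(reps):
            y = np.random.default_rng(2000 + rep).standard_normal(50)
            hits += math.isinf(select_lambda_ft(X, y, alpha).lam)
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert hits / reps == pytest.approx(1 - alpha, abs=3 * se)

    def test_membership_matches_direct_inequality(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((40, 2))
        y = X @ [1.0, -0.5] + rng.standard_normal(40)
        n, p = X.shape
        spec = svd_decompose(X)
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        sigma2 = float((y - X @ beta_hat) @ (y - X @ beta_hat)) / (n - p)
        alpha = 0.2
        res = select_lambda_ft(X, y, alpha)
        crit = p * sigma2 * stats.f.ppf(1 - alpha, p, n - p)
        for lam, expect_inside in ((res.lam, True), (res.lam * 1.05, False)):
            beta = spec.ridge_coef(y, lam)
            quad = float((beta - beta_hat) @ (X.T @ X) @ (beta - beta_hat))
            assert bool(quad <= crit * (1 + 1e-6)) == expect_inside

    def test_high_dimensions_rejected(self):
        X = np.random.default_rng(4).standard_normal((5, 8))
        with pytest.raises(ValueError, match="high dimensions"):
            select_lambda_ft(X, np.ones(5), 0.05)


class TestFStatistic:
    def test_hand_instance(self):
        X = np.ones((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        assert f_statistic(X, y, np.zeros(1)) == pytest.approx(12.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(55)
        X = rng.standard_normal((25, 4))
        pvals = []
        for _ in range(1000):
            y = rng.standard_normal(25)
            pvals.append(stats.f.sf(f_statistic(X, y, np.zeros(4)), 4, 21))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestConicClassify:
    def _design_with_gram(self, g1, g2):
        # X'X = diag(g1, g2) via a 2x2 diagonal design
        return np.diag([math.sqrt(g1), math.sqrt(g2)])

    def test_hyperbola_between_eigenvalues(self):
        X = self._design_with_gram(4.0, 1.0)
        assert conic_classify(X, 2.0) == "hyperbola"

    def test_ellipse_below_both(self):
        X = self._design_with_gram(4.0, 1.0)
        assert conic_classify(X, 0.5) == "ellipse"

    def test_parallel_lines_at_eigenvalue(self):
        X = self._design_with_gram(4.0, 1.0)
        assert conic_classify(X, 1.0) == "parallel_lines"

    def test_wrong_dimension(self):
        with pytest.raises(ValueError, match="two predictors"):
            conic_classify(np.eye(3), 1.0)

    def test_sign_agrees_with_diagonal_algebra(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            X = rng.standard_normal((12, 2))
            g2, g1 = np.linalg.eigvalsh(X.T @ X)
            c = rng.uniform(0.1 * g2, 1.5 * g1)
            expected = g1 * g2 * (g1 - c) * (g2 - c)
            got = conic_classify(X, c)
            if got == "hyperbola":
                assert expected < 0
            elif got == "ellipse":
                assert expected > 0


class TestDetectableCov:
    def test_flat_spectrum_zero(self):
        spec = svd_decompose(np.eye(3) * 2.0)
        assert detectable_cov(spec, np.ones(3), np.zeros(3), 1.0) == pytest.approx(0.0)

    def test_top_direction_positive(self):
        spec = svd_decompose(np.diag([2.0, 1.0]))  # gamma = (4, 1)
        beta = spec.V[:, 0]  # along the top eigenvector
        assert detectable_cov(spec, beta, np.zeros(2), 0.5) > 0

    def test_negative_spectral_exponent_negative(self):
        spec = svd_decompose(np.diag([2.0, 1.0]))
        beta = make_beta(spec, -2.0)
        assert detectable_cov(spec, beta, np.zeros(2), 0.5) < 0

    def test_null_point_rejected(self, small_design):
        _, spec = small_design
        with pytest.raises(ValueError, match="undefined"):
            detectable_cov(spec, np.ones(5), np.ones(5), 1.0)
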