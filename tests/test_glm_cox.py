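import math

import numpy as np
import pytest
from scipy import stats

from gtridge import (
    SurvivalData,
    brier_score,
    cox_loglik,
    cox_score,
    cvpl,
    gen_survival,
    gt_pvalue_asymptotic,
    ridge_cox_fit,
    ridge_glm_fit,
)
from gtridge.glm import logistic_loglik


@pytest.fixture(scope="module")
def cox_instance():
    rng = np.random.default_rng(17)
    X = rng.standard_normal((40, 3))
    surv = gen_survival(X, [0.7, -0.3, 0.0], censor_rate=0.3, seed=18)
    return X, surv


class TestRidgeGlmFit:
    def test_infinite_penalty(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        y = (np.arange(10) % 2).astype(float)
        assert np.all(ridge_glm_fit(X, y, "logistic", math.inf) == 0.0)

    def test_separable_data_finite(self):
        # perfectly separable: the penalty keeps the solution finite
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        beta = ridge_glm_fit(X, y, "logistic", 1.0)
        assert np.all(np.isfinite(beta)) and abs(beta[0]) < 10

    def test_matches_grid_search(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((20, 2))
        y = (rng.random(20) < 0.5).astype(float)
        lam = 0.5
        beta = ridge_glm_fit(X, y, "logistic", lam)
        obj_hat = logistic_loglik(X, y, beta) - lam * float(beta @ beta)
        b1, b2 = np.meshgrid(
            np.linspace(-2, 2, 200), np.linspace(-2, 2, 200), indexing="ij"
        )
        best = -np.inf
        for i in range(200):
            for j in range(200):
                b = np.array([b1[i, j], b2[i, j]])
                best = max(best, logistic_loglik(X, y, b) - lam * float(b @ b))
        assert obj_hat >= best - 1e-6

    def test_penalized_gradient_small(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((30, 5))
        y = (rng.random(30) < 0.4).astype(float)
        lam = 0.8
        beta = ridge_glm_fit(X, y, "logistic", lam)
        from gtridge.glm import logistic_score_info

        score, _ = logistic_score_info(X, y, beta)
        assert np.max(np.abs(score - 2 * lam * beta)) < 1e-8

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ridge_glm_fit(np.eye(3), np.array([0.0, 0.5, 1.0]), "logistic", 1.0)


class TestRidgeCoxFit:
    def test_infinite_penalty(self, cox_instance):
        X, surv = cox_instance
        assert np.all(ridge_cox_fit(X, surv, math.inf) == 0.0)

    def test_matches_1d_grid(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((25, 1))
        surv = gen_survival(X, [0.9], censor_rate=0.2, seed=22)
        lam = 0.7
        beta = ridge_cox_fit(X, surv, lam)
        grid = np.linspace(-2, 2, 4001)
        objs = [cox_loglik(X, surv, [b]) - lam * b * b for b in grid]
        oracle = grid[int(np.argmax(objs))]
        assert beta[0] == pytest.approx(oracle, abs=2e-3)

    def test_time_scale_invariance(self, cox_instance):
        X, surv = cox_instance
        doubled = SurvivalData(2.0 * surv.times, surv.status)
        np.testing.assert_allclose(
            ridge_cox_fit(X, surv, 1.0), ridge_cox_fit(X, doubled, 1.0), atol=1e-9
        )

    def test_zero_events_rejected(self):
        surv = SurvivalData(np.arange(1.0, 5.0), np.zeros(4))
        with pytest.raises(ValueError, match="event"):
            ridge_cox_fit(np.eye(4), surv, 1.0)


class TestCoxScore:
    def test_zero_at_unpenalized_mle(self, cox_instance):
        X, surv = cox_instance
        beta_mle = ridge_cox_fit(X, surv, 1e-9)
        score, _ = cox_score(X, surv, beta_mle)
        assert np.max(np.abs(score)) < 1e-5

    def test_hand_risk_set_oracle(self):
        # 5 subjects, one covariate, beta = 0: score is
        # sum over events of (x_i - mean of x over the risk set)
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.array([1, 0, 1, 0, 1])
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.5])
        surv = SurvivalData(times, status)
        expected = (
            (x[0] - x.mean())
            + (x[2] - x[2:].mean())
            + (x[4] - x[4])
        )
        score, _ = cox_score(x[:, None], surv, np.zeros(1))
        assert score[0] == pytest.approx(expected, abs=1e-12)

    def test_information_psd(self, cox_instance):
        X, surv = cox_instance
        for beta in (np.zeros(3), np.array([0.5, -0.2, 0.1])):
            _, info = cox_score(X, surv, beta)
            assert np.linalg.eigvalsh(info).min() > -1e-10

    def test_breslow_ties(self):
        # tied event times share one risk set under Breslow handling
        times = np.array([1.0, 1.0, 2.0])
        status = np.array([1, 1, 0])
        x = np.array([[1.0], [0.0], [-1.0]])
        surv = SurvivalData(times, status)
        ll = cox_loglik(x, surv, np.array([0.3]))
        eta = 0.3 * x[:, 0]
        denom = np.exp(eta).sum()
        expected = eta[0] + eta[1] - 2.0 * math.log(denom)
        assert ll == pytest.approx(expected, abs=1e-12)


class TestCoxGlobaltestCalibration:
    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(23)
        n, p = 200, 5
        X = rng.standard_normal((n, p))
        pvals = []
        for rep in range(400):
            surv = gen_survival(X, np.zeros(p), censor_rate=0.3, seed=3000 + rep)
            score, info = cox_score(X, surv, np.zeros(p))
            pvals.append(gt_pvalue_asymptotic(score, info).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCvpl:
    def test_null_model_closed_form(self, cox_instance):
        X, surv = cox_instance
        from sklearn.model_selection import StratifiedKFold

        got = cvpl(X, surv, math.inf, k=4, seed=5)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=5)
        zeros = np.zeros(X.shape[1])
        expected = 0.0
        for train, _ in skf.split(X, surv.status):
            expected += cox_loglik(X, surv, zeros) - cox_loglik(
                X[train], surv.subset(train), zeros
            )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self, cox_instance):
        X, surv = cox_instance
        assert cvpl(X, surv, 2.0, k=5, seed=9) == cvpl(X, surv, 2.0, k=5, seed=9)

    def test_equals_naive_refit(self, cox_instance):
        X, surv = cox_instance
        from sklearn.model_selection import StratifiedKFold

        lam, k, seed = 1.5, 4, 7
        got = cvpl(X, surv, lam, k=k, seed=seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        expected = 0.0
        for train, _ in skf.split(X, surv.status):
            b = ridge_cox_fit(X[train], surv.subset(train), lam)
            expected += cox_loglik(X, surv, b) - cox_loglik(
                X[train], surv.subset(train), b
            )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_grid_maximizer_behaviour(self):
        # strong signal: some finite penalty beats the null model end
        rng = np.random.default_rng(29)
        X = rng.standard_normal((80, 3))
        surv = gen_survival(X, [1.0, -0.8, 0.6], censor_rate=0.2, seed=30)
        grid = [0.5, 2.0, 8.0, 32.0, math.inf]
        vals = [cvpl(X, surv, lam, k=5, seed=3) for lam in grid]
        assert max(vals[:-1]) > vals[-1]


class TestBrierScore:
    def test_perfect_predictions(self):
        surv = SurvivalData(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        pred = np.array([0.0, 0.0, 1.0, 1.0])  # events at 1,2; survivors later
        assert brier_score(surv, pred, 2.5) == 0.0

    def test_constant_half_no_censoring(self):
        surv = SurvivalData(np.linspace(1, 10, 10), np.ones(10))
        assert brier_score(surv, np.full(10, 0.5), 5.5) == pytest.approx(0.25)

    def test_matches_termwise_ipcw_sum(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((60, 2))
        surv = gen_survival(X, [0.5, -0.5], censor_rate=0.4, seed=32)
        pred = rng.random(60)
        t_star = float(np.median(surv.times))
        got = brier_score(surv, pred, t_star)

        # independent IPCW evaluation via scikit-survival
        from sksurv.metrics import brier_score as sks_brier

        y = np.array(
            [(bool(d), t) for t, d in zip(surv.times, surv.status)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        _, (expected,) = sks_brier(y, y, pred, [t_star])
        assert got == pytest.approx(expected, rel=1e-6)

    def test_out_of_range_horizon(self):
        surv = SurvivalData(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            brier_score(surv, np.array([0.5, 0.5]), 5.0)
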