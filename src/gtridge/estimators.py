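"""Scikit-learn style estimators wrapping the tuning machinery.

Each estimator is a ridge model whose penalty is chosen at fit time by
one of the selection rules in this package:

``GlobaltestRidge``
    penalty from the globaltest confidence region at level 1−α
    (linear or logistic likelihood);
``ScheffeRidge``
    penalty from the classical F-test (Scheffé) region, n > p only;
``InformationCriterionRidge``
    penalty minimizing an information criterion on the effective model
    complexity;
``CrossValidationRidge``
    penalty from k-fold/LOOCV/GCV cross-validation;
``GlobaltestCoxRidge``
    Cox proportional-hazards version of the globaltest region selector.

All follow the fit/predict contract, expose ``get_params``/``set_params``
through ``BaseEstimator`` and store the selected penalty in ``lambda_``
(``numpy.inf`` when the null model is chosen).
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import cox as _cox
from . import criteria as _criteria
from . import glm as _glm
from .spectrum import default_grid, model_complexity, ridge_estimate_linear, svd_decompose
from .tuning import select_lambda_ft, select_lambda_gt

__all__ = [
    "GlobaltestRidge",
    "ScheffeRidge",
    "InformationCriterionRidge",
    "CrossValidationRidge",
    "GlobaltestCoxRidge",
]


class _BaseTunedRidge(RegressorMixin, BaseEstimator):
    """Shared plumbing: validation, optional centering/scaling, and the
    final linear ridge fit at the selected penalty."""

    def __init__(self, grid_size=100, center=False, scale=False):
        self.grid_size = grid_size
        self.center = center
        self.scale = scale

    def _prepare(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.x_mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        self.x_scale_ = np.ones(X.shape[1])
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            self.x_scale_ = sd
        Xw = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = float(np.mean(y)) if self.center else 0.0
        return Xw, np.asarray(y, float) - self.y_mean_

    def _finalize_linear(self, Xw, yw):
        spec = svd_decompose(Xw)
        lam = self.lambda_
        coef_w = (
            np.zeros(Xw.shape[1])
            if math.isinf(lam)
            else ridge_estimate_linear(spec, yw, lam)
        )
        self.coef_ = coef_w / self.x_scale_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.complexity_ = model_complexity(spec, lam)
        self.n_features_in_ = Xw.shape[1]

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


class GlobaltestRidge(_BaseTunedRidge):
    """Ridge regression tuned by the globaltest confidence region.

    Selects ``λ(α) = sup{λ : β̂_λ ∈ C_α^gt}`` — the least complex ridge
    solution the globaltest cannot reject at level α — and refits at the
    selected penalty.  ``lambda_`` is ``inf`` (null model, zero
    coefficients) exactly when the global null is not rejected, which
    under a true null happens with probability 1−α.

    Parameters
    ----------
    alpha : float in (0, 1)
        Test level; 1−α is the confidence level of the region.  0.05
        gives stringent type-I control, 0.5 tracks cross-validation.
    model : {"linear", "logistic"}
        Likelihood used for both the ridge path and the test.
    grid_size : int
        Size of the log-spaced λ search grid.
    tol : float
        Relative bisection tolerance in log λ.
    """

    def __init__(
        self,
        alpha=0.05,
        model="linear",
        grid_size=100,
        tol=1e-4,
        center=False,
        scale=False,
    ):
        super().__init__(grid_size=grid_size, center=center, scale=scale)
        self.alpha = alpha
        self.model = model
        self.tol = tol

    def fit(self, X, y):
        Xw, yw = self._prepare(X, y)
        mdl = "glm" if self.model == "logistic" else self.model
        if mdl == "glm":
            yw = np.asarray(y, float)  # no centering of a binary response
        res = select_lambda_gt(
            Xw, yw, self.alpha, model=mdl, grid_size=self.grid_size, log_tol=self.tol
        )
        self.lambda_ = res.lam
        self.alpha_ = res.alpha
        self.pvalue_null_ = res.pvalue_null
        self.result_ = res
        if mdl == "glm":
            self.coef_ = _glm.ridge_glm_fit(Xw, yw, "logistic", res.lam) / self.x_scale_
            self.intercept_ = 0.0
            self.n_features_in_ = Xw.shape[1]
        else:
            self._finalize_linear(Xw, yw)
        return self


class ScheffeRidge(_BaseTunedRidge):
    """Ridge regression tuned by the F-test (Scheffé) confidence region.

    Classical low-dimensional analogue of :class:`GlobaltestRidge`;
    requires n > p and a full-rank design.
    """

    def __init__(self, alpha=0.05, grid_size=100, tol=1e-4, center=False, scale=False):
        super().__init__(grid_size=grid_size, center=center, scale=scale)
        self.alpha = alpha
        self.tol = tol

    def fit(self, X, y):
        Xw, yw = self._prepare(X, y)
        res = select_lambda_ft(
            Xw, yw, self.alpha, grid_size=self.grid_size, log_tol=self.tol
        )
        self.lambda_ = res.lam
        self.alpha_ = res.alpha
        self.pvalue_null_ = res.pvalue_null
        self.result_ = res
        self._finalize_linear(Xw, yw)
        return self


class InformationCriterionRidge(_BaseTunedRidge):
    """Ridge regression tuned by an information criterion.

    Minimizes ``−2ℓ(λ) + penalty(mc, n, p)`` over the λ grid, with the
    effective complexity ``mc = Σ γᵢ/(γᵢ+λ)`` in place of a parameter
    count.  ``criterion`` is one of AIC, AICc, BIC, mBIC, mBIC2, GIC,
    RIC.
    """

    def __init__(self, criterion="AIC", grid_size=100, center=False, scale=False):
        super().__init__(grid_size=grid_size, center=center, scale=scale)
        self.criterion = criterion

    def fit(self, X, y):
        Xw, yw = self._prepare(X, y)
        spec = svd_decompose(Xw)
        res = _criteria.ic_select(
            Xw, yw, self.criterion, grid=default_grid(spec, size=self.grid_size)
        )
        self.lambda_ = res.lam
        self.result_ = res
        self._finalize_linear(Xw, yw)
        return self


class CrossValidationRidge(_BaseTunedRidge):
    """Ridge regression tuned by cross-validation (kCV, LOOCV or GCV)."""

    def __init__(
        self, method="kCV", k=5, random_state=0, grid_size=100, center=False, scale=False
    ):
        super().__init__(grid_size=grid_size, center=center, scale=scale)
        self.method = method
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        Xw, yw = self._prepare(X, y)
        spec = svd_decompose(Xw)
        res = _criteria.cv_select(
            Xw,
            yw,
            self.method,
            grid=default_grid(spec, size=self.grid_size),
            k=self.k,
            seed=self.random_state,
        )
        self.lambda_ = res.lam
        self.result_ = res
        self._finalize_linear(Xw, yw)
        return self


class GlobaltestCoxRidge(BaseEstimator):
    """Ridge-penalized Cox model tuned by the globaltest region.

    ``y`` may be a :class:`gtridge.cox.SurvivalData` or an (n, 2) array
    of (time, status).  ``predict(X)`` returns the linear risk score
    ``Xβ̂`` (higher = shorter expected survival).
    """

    def __init__(self, alpha=0.05, grid_size=100, tol=1e-4):
        self.alpha = alpha
        self.grid_size = grid_size
        self.tol = tol

    @staticmethod
    def _as_surv(y) -> _cox.SurvivalData:
        if isinstance(y, _cox.SurvivalData):
            return y
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("survival response must be SurvivalData or (n, 2) array")
        return _cox.SurvivalData(y[:, 0], y[:, 1])

    def fit(self, X, y):
        X = check_array(X)
        surv = self._as_surv(y)
        res = select_lambda_gt(
            X, surv, self.alpha, model="cox", grid_size=self.grid_size, log_tol=self.tol
        )
        self.lambda_ = res.lam
        self.alpha_ = res.alpha
        self.pvalue_null_ = res.pvalue_null
        self.result_ = res
        self.coef_ = _cox.ridge_cox_fit(X, surv, res.lam)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return check_array(X) @ self.coef_

    def score(self, X, y, k: int = 5, seed: int = 0) -> float:
        """Cross-validated partial likelihood at the selected penalty."""
        check_is_fitted(self, "lambda_")
        return _cox.cvpl(check_array(X), self._as_surv(y), self.lambda_, k=k, seed=seed)
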