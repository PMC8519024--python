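"""Baseline ridge tuning-parameter selectors: information criteria and
cross-validation.

Information criteria minimize ``−2 ℓ(λ) + penalty(mc, n, p)`` over the
penalty grid, where ``mc = Σᵢ γᵢ/(γᵢ+λ)`` is the effective model
complexity of the ridge fit and ℓ(λ) the Gaussian log-likelihood at
β̂_λ with the profile variance estimate ‖y − Xβ̂_λ‖²/n (a flag switches
to the ridge-penalized likelihood ℓ − λ‖β̂_λ‖² for sensitivity checks;
the unpenalized default is what keeps the light-penalty criteria AIC
and AICc overfitting in high dimensions, as they should).  The
factorial in the mBIC2 penalty is generalized to non-integer mc through
the log-gamma function.

Cross-validation selectors: seeded k-fold on held-out squared error, the
exact leave-one-out leverage formula, and generalized cross-validation
``(‖y − Xβ̂_λ‖²/n) / (1 − mc/n)²``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import gammaln
from sklearn.model_selection import KFold

from .spectrum import (
    DesignSpectrum,
    default_grid,
    model_complexity,
    ridge_estimate_linear,
    svd_decompose,
)
from .tuning import TuningResult

__all__ = ["CRITERIA", "ic_penalty", "ic_select", "cv_select", "gaussian_loglik"]


def _aic(mc, n, p):
    return 2.0 * mc


def _aicc(mc, n, p):
    if n <= mc + 1:
        raise ValueError("penalty undefined: AICc requires n > mc + 1")
    return (2.0 + 2.0 * (mc + 1.0) / (n - mc - 1.0)) * mc


def _bic(mc, n, p):
    return math.log(n) * mc


def _mbic(mc, n, p):
    if p <= 4:
        raise ValueError("mBIC requires p > 4")
    return (math.log(n) + 2.0 * math.log(p / 4.0 - 1.0)) * mc


def _mbic2(mc, n, p):
    # mc! generalized as Γ(mc + 1) for continuous effective complexity
    return (math.log(n) + 2.0 * math.log(p / 4.0)) * mc - 2.0 * gammaln(mc + 1.0)


def _gic(mc, n, p):
    return math.log(math.log(n)) * math.log(p) * mc


def _ric(mc, n, p):
    return 2.0 * math.log(p) * mc


CRITERIA = {
    "AIC": _aic,
    "AICc": _aicc,
    "BIC": _bic,
    "mBIC": _mbic,
    "mBIC2": _mbic2,
    "GIC": _gic,
    "RIC": _ric,
}


def ic_penalty(name: str, mc: float, n: int, p: int) -> float:
    """Model-complexity penalty of the named information criterion."""
    if mc < 0:
        raise ValueError("model complexity must be nonnegative")
    try:
        fn = CRITERIA[name]
    except KeyError:
        raise ValueError(f"unknown criterion {name!r}") from None
    return float(fn(float(mc), n, p))


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood with the profile variance σ̂² = rss/n."""
    if rss <= 0.0:
        raise ValueError("residual sum of squares must be positive")
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def _path_quantities(spec: DesignSpectrum, y: np.ndarray, grid: np.ndarray):
    """Per-λ residual sum of squares, mc and ‖β̂_λ‖² on a grid with ∞."""
    rss = np.empty(grid.size)
    mc = np.empty(grid.size)
    b2 = np.empty(grid.size)
    for i, lam in enumerate(grid):
        beta_norm2 = 0.0
        if math.isinf(lam):
            resid = y
        else:
            fitted = spec.fitted(y, lam)
            resid = y - fitted
            coef = ridge_estimate_linear(spec, y, lam)
            beta_norm2 = float(coef @ coef)
        rss[i] = float(resid @ resid)
        mc[i] = model_complexity(spec, lam)
        b2[i] = beta_norm2
    return rss, mc, b2


def _with_sentinel(grid: np.ndarray) -> np.ndarray:
    grid = np.sort(np.asarray(grid, dtype=float)[np.isfinite(grid)])[::-1]
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    return np.concatenate(([np.inf], grid))


def ic_select(
    X,
    y,
    name: str,
    grid: np.ndarray | None = None,
    model: str = "linear",
    penalized_loglik: bool = False,
) -> TuningResult:
    """Choose λ minimizing ``−2 ℓ(λ) + penalty(mc, n, p)`` on the grid.

    ``ℓ(λ)`` is by default the (unpenalized) Gaussian log-likelihood at
    the ridge solution β̂_λ with profile variance; setting
    ``penalized_loglik=True`` subtracts λ‖β̂_λ‖² for sensitivity checks.
    Grid points where the penalty is undefined (e.g. AICc with
    mc ≥ n − 1) are skipped.  The grid always includes the ∞ sentinel
    (null model); ties are broken toward the larger λ.
    """
    if model != "linear":
        raise NotImplementedError("information criteria implemented for the linear model")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    spec = svd_decompose(X)
    grid = _with_sentinel(default_grid(spec) if grid is None else grid)
    rss, mc, b2 = _path_quantities(spec, y, grid)
    best_lam, best_crit = None, np.inf
    for lam, r, m, bb in zip(grid, rss, mc, b2):
        ll = gaussian_loglik(r, n)
        if penalized_loglik and not math.isinf(lam):
            ll -= lam * bb
        try:
            pen = ic_penalty(name, m, n, p)
        except ValueError:
            if math.isinf(lam):
                raise
            continue
        crit = -2.0 * ll + pen
        if crit < best_crit:  # strict: ties keep the earlier (larger) λ
            best_lam, best_crit = float(lam), crit
    return TuningResult(lam=best_lam, alpha=float("nan"), pvalue_null=float("nan"))


def cv_select(
    X,
    y,
    name: str = "kCV",
    grid: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
) -> TuningResult:
    """Cross-validation choice of λ on the grid (incl. the ∞ sentinel).

    ``kCV`` minimizes the mean held-out squared error with seeded folds;
    ``LOOCV`` uses the exact leverage identity
    ``n⁻¹ Σᵢ ((yᵢ − ŷᵢ)/(1 − hᵢᵢ))²`` with hᵢᵢ from the ridge hat matrix;
    ``GCV`` minimizes ``(‖y − Xβ̂_λ‖²/n)/(1 − mc/n)²``.  Ties go to the
    larger λ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    spec = svd_decompose(X)
    grid = _with_sentinel(default_grid(spec) if grid is None else grid)

    if name == "kCV":
        if k < 2:
            raise ValueError("need at least two folds")
        errs = np.zeros(grid.size)
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for train, test in kf.split(X):
            sub = svd_decompose(X[train])
            for i, lam in enumerate(grid):
                beta = ridge_estimate_linear(sub, y[train], lam)
                resid = y[test] - X[test] @ beta
                errs[i] += float(resid @ resid)
        scores = errs / n
    elif name == "LOOCV":
        scores = np.empty(grid.size)
        for i, lam in enumerate(grid):
            h = spec.hat_diag(lam)
            resid = y - spec.fitted(y, lam)
            scores[i] = float(np.mean((resid / (1.0 - h)) ** 2))
    elif name == "GCV":
        scores = np.full(grid.size, np.inf)
        for i, lam in enumerate(grid):
            mc = model_complexity(spec, lam)
            if mc >= n:
                warnings.warn(
                    f"GCV denominator vanishes at lambda={lam:g} (mc >= n); "
                    "grid point skipped"
                )
                continue
            resid = y - spec.fitted(y, lam)
            scores[i] = (float(resid @ resid) / n) / (1.0 - mc / n) ** 2
    else:
        raise ValueError(f"unknown cross-validation method {name!r}")

    best = int(np.argmin(scores))  # argmin keeps the first (largest λ) on ties
    return TuningResult(
        lam=float(grid[best]), alpha=float("nan"), pvalue_null=float("nan")
    )
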