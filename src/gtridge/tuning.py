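"""Tuning-parameter selection by confidence-region membership.

The selected penalty is

    λ(α) = sup{λ ∈ [0, ∞) : β̂_λ ∈ C_α},

the least complex ridge solution still inside the 1−α confidence region
of the coefficient vector.  The region is obtained by inverting either
the globaltest (usable in any dimension, for linear, logistic and Cox
models) or the F test (Scheffé ellipsoid, linear models with n > p
only).  Membership of β̂_λ at level α is equivalent to the test of
H₀: β = β̂_λ having p-value ≥ α, so the two-way map between λ and α is

    α(λ) = inf{α : β̂_λ ∈ C_α} = p-value at β̂_λ,

a nonincreasing function of λ.  When even the null model β̂_∞ = 0 sits
inside the region the ∞ sentinel is returned — this happens with
probability 1−α under the global null, which is the method's testimation
guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import cox as _cox
from . import glm as _glm
from .globaltest import gt_pvalue_asymptotic, gt_pvalue_linear
from .spectrum import DesignSpectrum, default_grid, ridge_estimate_linear, svd_decompose

__all__ = [
    "RegionSpec",
    "TuningResult",
    "alpha_of_lambda",
    "select_lambda_gt",
    "select_lambda_ft",
    "f_statistic",
    "conic_classify",
    "detectable_cov",
]


@dataclass(frozen=True)
class RegionSpec:
    """A 1−α confidence region defined by test inversion."""

    test: str  # "globaltest" or "ftest"
    alpha: float
    critical: float

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.critical <= 0:
            raise ValueError("critical value must be positive")


@dataclass(frozen=True)
class TuningResult:
    """Selected penalty and diagnostics.

    ``lam`` is ``inf`` exactly when the p-value of the global null
    (β₀ = 0) is at least ``alpha``.
    """

    lam: float
    alpha: float
    pvalue_null: float
    crossing_bracket: tuple[float, float] | None = None
    n_evals: int = 0
    multi_crossing: bool | None = None
    no_crossing: bool = False


def _pvalue_profile_linear(X, y, spec: DesignSpectrum):
    """Return a closure λ ↦ globaltest p-value of H₀: β = β̂_λ."""
    y = np.asarray(y, dtype=float)

    def pval(lam: float) -> float:
        beta = ridge_estimate_linear(spec, y, lam)
        resid = y - X @ beta
        denom = float(resid @ resid)
        if denom <= 0.0:
            return 1.0
        score = X.T @ resid
        s = float(score @ score) / denom
        return gt_pvalue_linear(spec, s)

    return pval


def _pvalue_profile_glm(X, y):
    def pval(lam: float) -> float:
        beta = _glm.ridge_glm_fit(X, y, "logistic", lam)
        score, info = _glm.logistic_score_info(X, y, beta)
        return gt_pvalue_asymptotic(score, info).pvalue

    return pval


def _pvalue_profile_cox(X, surv):
    def pval(lam: float) -> float:
        beta = _cox.ridge_cox_fit(X, surv, lam)
        score, info = _cox.cox_score(X, surv, beta)
        return gt_pvalue_asymptotic(score, info).pvalue

    return pval


def _profile(X, y, model: str, spec: DesignSpectrum | None = None):
    X = np.asarray(X, dtype=float)
    if model == "linear":
        if spec is None:
            spec = svd_decompose(X)
        return _pvalue_profile_linear(X, np.asarray(y, float), spec), spec
    if model in ("glm", "logistic"):
        if spec is None:
            spec = svd_decompose(X)
        return _pvalue_profile_glm(X, np.asarray(y, float)), spec
    if model == "cox":
        if spec is None:
            spec = svd_decompose(X)
        if not isinstance(y, _cox.SurvivalData):
            raise TypeError("cox model requires SurvivalData response")
        return _pvalue_profile_cox(X, y), spec
    raise ValueError(f"unknown model {model!r}")


def alpha_of_lambda(X, y, lam: float, model: str = "linear") -> float:
    """The smallest level α at which β̂_λ is inside the region C_α^gt.

    Equals the globaltest p-value of H₀: β = β̂_λ; nonincreasing in λ,
    going from ≈1 near λ = 0 (for n > p) down to the p-value of the
    global null at λ = ∞.
    """
    pval, _ = _profile(X, y, model)
    return pval(lam)


def _select_sup(
    pval,
    alpha: float,
    grid: np.ndarray,
    log_tol: float = 1e-4,
    full_scan: bool = False,
) -> TuningResult:
    """Generic sup-search shared by the globaltest and F-test selectors.

    ``pval`` maps λ to the membership p-value.  Scans the decreasing grid
    from the top so the *largest* crossing is found even if the profile
    is numerically non-monotone, then refines the bracketing interval by
    bisection in log λ.  Boundary ties (p-value exactly α) count as
    inside the region.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_evals = 1
    p_inf = pval(math.inf)
    if p_inf >= alpha:
        return TuningResult(
            lam=math.inf, alpha=alpha, pvalue_null=p_inf, n_evals=n_evals
        )
    grid = np.sort(np.asarray(grid, dtype=float)[np.isfinite(grid)])[::-1]
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    pvals = []
    cross_idx = None
    for i, lam in enumerate(grid):
        p = pval(lam)
        n_evals += 1
        pvals.append(p)
        if p >= alpha:
            cross_idx = i
            if not full_scan:
                break
    if cross_idx is None:
        # even the least-penalized grid point is rejected: no acceptable
        # model on the grid; report the smallest grid value with a flag
        return TuningResult(
            lam=float(grid[-1]),
            alpha=alpha,
            pvalue_null=p_inf,
            n_evals=n_evals,
            no_crossing=True,
        )
    multi = None
    if full_scan:
        inside = np.asarray(pvals) >= alpha
        multi = bool(np.sum(np.diff(inside.astype(int)) != 0) > 1)
    if cross_idx == 0:
        # inside already at the largest finite grid point; treat the grid
        # top as the selected penalty (the region extends beyond the grid)
        return TuningResult(
            lam=float(grid[0]),
            alpha=alpha,
            pvalue_null=p_inf,
            crossing_bracket=(float(grid[0]), math.inf),
            n_evals=n_evals,
            multi_crossing=multi,
        )
    lo, hi = float(grid[cross_idx]), float(grid[cross_idx - 1])  # p(lo)>=a>p(hi)
    bracket = (lo, hi)
    while math.log10(hi / lo) > log_tol:
        mid = math.sqrt(lo * hi)
        n_evals += 1
        if pval(mid) >= alpha:
            lo = mid
        else:
            hi = mid
    return TuningResult(
        lam=lo,
        alpha=alpha,
        pvalue_null=p_inf,
        crossing_bracket=bracket,
        n_evals=n_evals,
        multi_crossing=multi,
    )


def select_lambda_gt(
    X,
    y,
    alpha: float,
    model: str = "linear",
    grid: np.ndarray | None = None,
    grid_size: int = 100,
    log_tol: float = 1e-4,
    full_scan: bool = False,
) -> TuningResult:
    """Globaltest confidence-region choice of the ridge penalty.

    Returns ``λ_gt(α) = sup{λ : β̂_λ ∈ C_α^gt}``; the ∞ sentinel when the
    whole path lies inside the region (equivalently, the global-null
    p-value is at least α).
    """
    X = np.asarray(X, dtype=float)
    pval, spec = _profile(X, y, model)
    if grid is None:
        grid = default_grid(spec, size=grid_size)
    return _select_sup(pval, alpha, grid, log_tol=log_tol, full_scan=full_scan)


def f_statistic(X, y, beta0) -> float:
    """Classical F statistic ``‖Xβ̂ − Xβ₀‖² / (p σ̂²)`` with
    ``σ̂² = ‖y − Xβ̂‖²/(n−p)``; follows F(p, n−p) under H₀: β = β₀."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("F-test inapplicable in high dimensions (requires n > p)")
    spec = svd_decompose(X)
    if spec.rank < p:
        raise ValueError("design matrix is rank deficient")
    beta_hat = ridge_estimate_linear(spec, y, 0.0)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / (n - p)
    diff = X @ (beta_hat - np.asarray(beta0, dtype=float))
    return float(diff @ diff) / (p * sigma2)


def select_lambda_ft(
    X,
    y,
    alpha: float,
    grid: np.ndarray | None = None,
    grid_size: int = 100,
    log_tol: float = 1e-4,
    full_scan: bool = False,
) -> TuningResult:
    """Scheffé (F-test) confidence-region choice of the ridge penalty.

    Same sup definition as :func:`select_lambda_gt` but membership is
    ``(β₀−β̂)ᵀXᵀX(β₀−β̂) ≤ p σ̂² f^α_{p,n−p}``.  Linear models with
    n > p and full column rank only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("F-test inapplicable in high dimensions (requires n > p)")
    spec = svd_decompose(X)
    if spec.rank < p:
        raise ValueError("design matrix is rank deficient")
    beta_hat = ridge_estimate_linear(spec, y, 0.0)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / (n - p)
    fitted_hat = X @ beta_hat

    def pval(lam: float) -> float:
        beta = ridge_estimate_linear(spec, y, lam)
        diff = fitted_hat - X @ beta
        t_stat = float(diff @ diff) / (p * sigma2)
        return float(stats.f.sf(t_stat, p, n - p))

    if grid is None:
        grid = default_grid(spec, size=grid_size)
    return _select_sup(pval, alpha, grid, log_tol=log_tol, full_scan=full_scan)


def conic_classify(X, c: float) -> str:
    """Classify the p = 2 globaltest region boundary as a conic section.

    The boundary is a quadratic curve whose type is decided by the sign
    of ``δ = det(XᵀXXᵀX − c·XᵀX)``: positive → ellipse, zero → pair of
    parallel lines, negative → hyperbola.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("classification defined for two predictors only")
    m = X.T @ X
    delta = float(np.linalg.det(m @ m - c * m))
    gamma = np.linalg.eigvalsh(m)
    scale = float(gamma[-1] ** 3 * max(gamma[0], gamma[-1] * 1e-16))
    if abs(delta) <= 1e-9 * scale:
        return "parallel_lines"
    return "ellipse" if delta > 0 else "hyperbola"


def detectable_cov(spec: DesignSpectrum, beta, beta0, sigma2: float) -> float:
    """Covariance of (γ, r²) deciding globaltest detectability of β₀.

    With ``rᵢ² = γᵢ (β−β₀)ᵀVᵢ(β−β₀) / ((β−β₀)ᵀXᵀX(β−β₀) + nσ²)``, a
    positive covariance between the eigenvalues γ and the per-component
    explained-variance fractions r² means large-variance principal
    components carry more of the signal, where the globaltest has good
    power (β₀ lies in the detectable region D).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    d = np.asarray(beta, dtype=float) - np.asarray(beta0, dtype=float)
    if not np.any(d):
        raise ValueError("direction undefined at the null point")
    proj = spec.V.T @ d  # vᵢᵀ(β−β₀)
    quad = float(np.sum(spec.gamma * proj**2))  # (β−β₀)ᵀXᵀX(β−β₀)
    r2 = spec.gamma * proj**2 / (quad + spec.n * sigma2)
    return float(np.cov(spec.gamma, r2)[0, 1])
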