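"""The globaltest: a score test of H₀: β = β₀ against high-dimensional
alternatives.

The statistic is ``S_{β₀} = sᵀs``, the squared norm of the score vector.
For the Gaussian linear model it reduces to the ratio

    S_{β₀} = ‖Xᵀ(y − Xβ₀)‖² / ‖y − Xβ₀‖²,

whose null distribution is exact and free of σ²: ``P(S > c)`` equals the
probability that the indefinite quadratic form ``εᵀ(XXᵀ − c·I)ε`` is
positive for ε standard normal, i.e. an Imhof tail with weights
``{γᵢ − c}`` plus ``−c`` repeated n − rank times.  For other GLMs and the
Cox model the null is the asymptotic weighted chi-squared ``Σᵢ ωᵢ χ²₁``
with ωᵢ the eigenvalues of the score covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .quadform import imhof_tail
from .spectrum import DesignSpectrum, svd_decompose

__all__ = [
    "GlobaltestResult",
    "gt_statistic_linear",
    "gt_pvalue_linear",
    "gt_critical_value",
    "gt_statistic_score",
    "gt_pvalue_asymptotic",
    "gt_test_linear",
]

# eigenvalues of the score covariance below this (relative) are dropped
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class GlobaltestResult:
    """Outcome of one globaltest evaluation."""

    statistic: float
    weights: np.ndarray
    pvalue: float
    method: str  # "exact_ratio" or "asymptotic"
    beta0: np.ndarray | None = None


def gt_statistic_linear(X, y, beta0) -> float:
    """Ratio statistic ``‖Xᵀ(y − Xβ₀)‖² / ‖y − Xβ₀‖²``.

    Invariant to rescaling of the residual; raises if the fit is
    saturated (zero residual) since the ratio is then undefined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    resid = y - X @ beta0
    denom = float(resid @ resid)
    if denom == 0.0:
        raise ValueError("saturated fit; statistic undefined")
    score = X.T @ resid
    return float(score @ score) / denom


def _null_weights(spec: DesignSpectrum, s_obs: float) -> np.ndarray:
    """Weights of the indefinite form ``εᵀ(XXᵀ − s·I)ε``."""
    return np.concatenate(
        [spec.gamma - s_obs, np.full(spec.n - spec.rank, -s_obs)]
    )


def gt_pvalue_linear(spec: DesignSpectrum, s_obs: float) -> float:
    """Exact linear-model null tail ``P(S > s_obs)``.

    Free of σ² because the statistic is scale-invariant in the residual.
    Returns 1 at ``s_obs = 0`` (S is almost surely positive) and 0 for
    ``s_obs ≥ γ₁`` (the form is then nonpositive definite).
    """
    if s_obs < 0:
        raise ValueError("observed statistic must be nonnegative")
    if s_obs == 0.0:
        return 1.0
    if s_obs >= spec.gamma[0]:
        return 0.0
    return imhof_tail(_null_weights(spec, s_obs), 0.0)


def gt_critical_value(spec: DesignSpectrum, alpha: float) -> float:
    """The 1−α quantile c_α of the exact linear-model null of S.

    Solves ``gt_pvalue_linear(spec, c) = α`` by bracketing in (0, γ₁);
    the p-value is continuous and strictly decreasing on that interval.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    hi = spec.gamma[0]
    lo = hi * 1e-14
    return float(
        brentq(
            lambda c: gt_pvalue_linear(spec, c) - alpha,
            lo,
            hi * (1.0 - 1e-14),
            xtol=1e-14 * hi,
            rtol=1e-12,
        )
    )


def gt_statistic_score(score) -> float:
    """``sᵀs`` for an arbitrary score vector (the constant trace term of
    the original statistic does not depend on the response and is
    dropped)."""
    s = np.asarray(score, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("score vector must be finite")
    return float(s @ s)


def gt_pvalue_asymptotic(score, score_cov, beta0=None) -> GlobaltestResult:
    """Asymptotic globaltest for GLM/Cox scores.

    Under H₀ the score is asymptotically N(0, Σ) with Σ the score
    covariance (observed information), so ``sᵀs`` is a weighted
    chi-squared ``Σᵢ ωᵢ χ²₁`` with ωᵢ the eigenvalues of Σ.
    """
    s = np.asarray(score, dtype=float).ravel()
    cov = np.asarray(score_cov, dtype=float)
    if cov.shape != (s.size, s.size):
        raise ValueError("score covariance has incompatible shape")
    eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    top = eig[-1]
    if top <= 0:
        raise ValueError("degenerate score covariance")
    if eig[0] < -_EIG_TOL * top:
        raise ValueError("score covariance is not positive semidefinite")
    omega = eig[eig > _EIG_TOL * top]
    stat = gt_statistic_score(s)
    pvalue = 1.0 if stat == 0.0 else imhof_tail(omega, stat)
    return GlobaltestResult(
        statistic=stat,
        weights=omega,
        pvalue=pvalue,
        method="asymptotic",
        beta0=None if beta0 is None else np.asarray(beta0, dtype=float),
    )


def gt_test_linear(X, y, beta0=None, spec: DesignSpectrum | None = None) -> GlobaltestResult:
    """Convenience wrapper: exact linear-model globaltest of H₀: β = β₀."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if beta0 is None:
        beta0 = np.zeros(X.shape[1])
    if spec is None:
        spec = svd_decompose(X)
    stat = gt_statistic_linear(X, y, beta0)
    return GlobaltestResult(
        statistic=stat,
        weights=_null_weights(spec, stat),
        pvalue=gt_pvalue_linear(spec, stat),
        method="exact_ratio",
        beta0=np.asarray(beta0, dtype=float),
    )
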