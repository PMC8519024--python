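"""Singular-value machinery for the design matrix and the closed-form ridge path.

The whole package runs off one factorization of the design matrix,
``X = U Γ^{1/2} Vᵀ``, where ``γ₁ ≥ … ≥ γ_r > 0`` are the nonzero eigenvalues
of ``XᵀX``.  The linear ridge estimator, the effective model complexity,
leverage values and the exact globaltest null distribution are all simple
functions of these factors, so computing them once per design makes every
downstream evaluation O(n·r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignSpectrum",
    "RidgePath",
    "svd_decompose",
    "ridge_estimate_linear",
    "ridge_path",
    "model_complexity",
    "default_grid",
]

#: relative singular-value cutoff below which directions are treated as null
RANK_TOL = 1e-12


@dataclass(frozen=True)
class DesignSpectrum:
    """Thin SVD of a design matrix with zero singular values removed.

    Attributes
    ----------
    n, p : int
        Number of samples and predictors.
    rank : int
        Number of retained singular values.
    U : ndarray of shape (n, rank)
        Left singular vectors (orthonormal columns).
    V : ndarray of shape (p, rank)
        Right singular vectors / principal-component directions.
    gamma : ndarray of shape (rank,)
        Nonzero eigenvalues of ``XᵀX``, sorted in decreasing order.
    """

    n: int
    p: int
    rank: int
    U: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)

    def reconstruct(self) -> np.ndarray:
        """Return ``U Γ^{1/2} Vᵀ`` (equals X up to the rank truncation)."""
        return (self.U * np.sqrt(self.gamma)) @ self.V.T

    def ridge_coef(self, y: np.ndarray, lam: float) -> np.ndarray:
        """Ridge coefficients ``Σᵢ γᵢ^{1/2}/(γᵢ+λ) vᵢ uᵢᵀ y``."""
        return ridge_estimate_linear(self, y, lam)

    def complexity(self, lam: float) -> float:
        """Effective model complexity ``mc(λ) = Σᵢ γᵢ/(γᵢ+λ)``."""
        return model_complexity(self, lam)

    def hat_diag(self, lam: float) -> np.ndarray:
        """Diagonal of the ridge hat matrix ``X (XᵀX + λI)⁻¹ Xᵀ``."""
        if math.isinf(lam):
            return np.zeros(self.n)
        shrink = self.gamma / (self.gamma + lam)
        return np.einsum("ij,j,ij->i", self.U, shrink, self.U)

    def fitted(self, y: np.ndarray, lam: float) -> np.ndarray:
        """Fitted values ``X β̂_λ`` without forming the coefficients."""
        if math.isinf(lam):
            return np.zeros(self.n)
        shrink = self.gamma / (self.gamma + lam)
        return self.U @ (shrink * (self.U.T @ y))


@dataclass(frozen=True)
class RidgePath:
    """Ridge solution path on a decreasing λ grid starting at the ∞ sentinel.

    ``lambdas[0]`` is always ``inf`` and ``coefficients[0]`` exactly zero;
    ``complexity`` is nonincreasing in λ (so nondecreasing along the stored
    order).
    """

    lambdas: np.ndarray
    coefficients: np.ndarray  # (len(lambdas), p)
    complexity: np.ndarray
    loglik: np.ndarray | None = None


def svd_decompose(X: np.ndarray, tol: float = RANK_TOL) -> DesignSpectrum:
    """Factor ``X = U Γ^{1/2} Vᵀ`` keeping only nonzero singular values.

    Parameters
    ----------
    X : array-like of shape (n, p)
        Design matrix; must be finite with at least one nonzero entry.
    tol : float
        Singular values below ``tol`` times the largest are dropped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    if sv.size == 0 or sv[0] <= 0.0:
        raise ValueError("degenerate design: all-zero matrix")
    keep = sv > tol * sv[0]
    rank = int(keep.sum())
    return DesignSpectrum(
        n=X.shape[0],
        p=X.shape[1],
        rank=rank,
        U=np.ascontiguousarray(U[:, keep]),
        V=np.ascontiguousarray(Vt[keep].T),
        gamma=sv[keep] ** 2,
    )


def ridge_estimate_linear(
    spec: DesignSpectrum, y: np.ndarray, lam: float
) -> np.ndarray:
    """Closed-form linear ridge solution at penalty ``lam``.

    Returns ``Σᵢ γᵢ^{1/2}/(γᵢ+λ) vᵢ uᵢᵀ y``, which equals
    ``(XᵀX + λI)⁻¹Xᵀy`` for λ > 0 and the minimum-norm least-squares
    solution at λ = 0.  At the ∞ sentinel the exact zero vector is
    returned.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (spec.n,):
        raise ValueError(f"response has length {y.shape}, expected ({spec.n},)")
    if math.isinf(lam):
        return np.zeros(spec.p)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    w = np.sqrt(spec.gamma) / (spec.gamma + lam)
    return spec.V @ (w * (spec.U.T @ y))


def model_complexity(spec: DesignSpectrum, lam: float) -> float:
    """Effective model complexity ``mc(λ) = Σᵢ γᵢ/(γᵢ+λ)``.

    Continuous analogue of the parameter count: ``mc(0) = rank(X)`` and
    ``mc(∞) = 0``.
    """
    if math.isinf(lam):
        return 0.0
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    return float(np.sum(spec.gamma / (spec.gamma + lam)))


def default_grid(
    spec: DesignSpectrum, size: int = 100, span: float = 1e4
) -> np.ndarray:
    """Decreasing log-spaced λ grid covering the mc transition region.

    Spans ``[γ_min/span, γ₁·span]``, which takes mc from essentially
    rank(X) down to essentially zero.  The ∞ sentinel is *not* included;
    path/selection code prepends it.
    """
    if size < 1:
        raise ValueError("grid size must be positive")
    lo = spec.gamma[-1] / span
    hi = spec.gamma[0] * span
    return np.logspace(math.log10(hi), math.log10(lo), size)


def ridge_path(
    spec: DesignSpectrum, y: np.ndarray, grid: np.ndarray | None = None
) -> RidgePath:
    """Materialize the ridge solution path on a λ grid.

    The grid must be positive and finite; it is sorted decreasing and the
    ∞ sentinel is prepended, so the path always starts at the null model.
    """
    if grid is None:
        grid = default_grid(spec)
    grid = np.asarray(grid, dtype=float)
    grid = grid[np.isfinite(grid)]
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    if np.any(grid <= 0):
        raise ValueError("grid values must be positive")
    grid = np.sort(grid)[::-1]
    lambdas = np.concatenate(([np.inf], grid))
    coefs = np.empty((lambdas.size, spec.p))
    mc = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        coefs[i] = ridge_estimate_linear(spec, y, lam)
        mc[i] = model_complexity(spec, lam)
    return RidgePath(lambdas=lambdas, coefficients=coefs, complexity=mc)
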