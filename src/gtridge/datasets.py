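"""Seeded synthetic-data generators.

Designs with controllable correlation structure and spectral decay stand
in for the gene-expression matrices the tuning methods are meant for
(hundreds of samples, tens to thousands of correlated predictors), and a
proportional-hazards generator with exponential baseline and independent
exponential censoring provides survival responses for the Cox layer.
All generators are pure functions of their spec: identical parameters
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .cox import SurvivalData

__all__ = ["DesignSpec", "gen_design", "gen_survival"]


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one synthetic design matrix.

    kind : "iid" (standard normal entries), "ar1" (rows with covariance
        ρ^|j−k|), or "spiked" (eigenvalues of XᵀX/n decaying like
        j^−decay).
    """

    kind: str
    n: int
    p: int
    rho: float = 0.0
    decay: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("iid", "ar1", "spiked"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.n < 1 or self.p < 1:
            raise ValueError("dimensions must be positive")
        if self.kind == "ar1" and not 0.0 <= self.rho < 1.0:
            raise ValueError("AR(1) correlation must be in [0, 1)")
        if self.kind == "spiked" and self.decay <= 0.0:
            raise ValueError("spectral decay exponent must be positive")


def gen_design(spec: DesignSpec) -> np.ndarray:
    """Draw the n×p design matrix described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "iid":
        return rng.standard_normal((spec.n, spec.p))
    if spec.kind == "ar1":
        z = rng.standard_normal((spec.n, spec.p))
        if spec.rho == 0.0:
            return z
        cov = toeplitz(spec.rho ** np.arange(spec.p))
        return z @ cholesky(cov, lower=False)
    # spiked: X = Z D^{1/2} Qᵀ so that E[XᵀX/n] = Q D Qᵀ with D_j ∝ j^−decay
    z = rng.standard_normal((spec.n, spec.p))
    d = np.arange(1, spec.p + 1, dtype=float) ** (-spec.decay)
    q, _ = np.linalg.qr(rng.standard_normal((spec.p, spec.p)))
    return (z * np.sqrt(d)) @ q.T


def gen_survival(
    X,
    beta,
    baseline_rate: float = 1.0,
    censor_rate: float = 0.5,
    seed: int = 0,
) -> SurvivalData:
    """Right-censored survival times from a proportional-hazards model.

    Event times are exponential with hazard ``baseline_rate·exp(xᵢᵀβ)``;
    censoring times are independent exponential with rate
    ``censor_rate`` (0 disables censoring).  Raises if no events result.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline hazard rate must be positive")
    if censor_rate < 0:
        raise ValueError("censoring rate must be nonnegative")
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    event = rng.exponential(1.0, size=X.shape[0]) / (baseline_rate * np.exp(eta))
    if censor_rate > 0:
        cens = rng.exponential(1.0 / censor_rate, size=X.shape[0])
    else:
        cens = np.full(X.shape[0], np.inf)
    times = np.minimum(event, cens)
    status = (event <= cens).astype(int)
    if status.sum() == 0:
        raise ValueError("no events in the generated sample")
    return SurvivalData(times, status)
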