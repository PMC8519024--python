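"""Ridge-penalized logistic regression by damped Newton iterations.

The objective is the penalized log-likelihood ``ℓ(β) − λ‖β‖²`` (note the
penalty is λ times the *squared* L2 norm, so its gradient contributes
−2λβ).  For λ > 0 the objective is strictly concave, which guarantees a
unique finite maximizer even on separable data.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ridge_glm_fit", "logistic_loglik", "logistic_score_info"]

_MAX_ITER = 50
_GRAD_TOL = 1e-8


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_loglik(X, y, beta) -> float:
    """Bernoulli log-likelihood at coefficients ``beta`` (no intercept)."""
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    # log(1 + e^eta) computed stably
    return float(np.sum(np.asarray(y, float) * eta) - np.sum(np.logaddexp(0.0, eta)))


def logistic_score_info(X, y, beta):
    """Score vector and observed information of the (unpenalized)
    logistic log-likelihood at ``beta``."""
    X = np.asarray(X, float)
    mu = _sigmoid(X @ np.asarray(beta, float))
    score = X.T @ (np.asarray(y, float) - mu)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    return score, info


def ridge_glm_fit(X, y, family: str = "logistic", lam: float = 1.0) -> np.ndarray:
    """Maximize ``ℓ(β) − λ‖β‖²`` for the logistic model.

    Parameters
    ----------
    X : (n, p) design matrix.
    y : binary response in {0, 1}.
    family : only ``"logistic"`` is implemented; the linear model has a
        closed form (see :mod:`gtridge.spectrum`).
    lam : penalty λ > 0, or ``inf`` for the exact zero vector.  λ = 0 is
        accepted but the MLE must exist (non-separable data).

    Returns
    -------
    ndarray of shape (p,)
        The maximizer; the penalized gradient has sup-norm below 1e-8.
    """
    if family != "logistic":
        raise ValueError(f"unsupported family {family!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("logistic response must be binary 0/1")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design")
    if math.isinf(lam):
        return np.zeros(p)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")

    beta = np.zeros(p)
    obj = logistic_loglik(X, y, beta)  # penalty is 0 at beta = 0
    trace = []
    for it in range(_MAX_ITER):
        score, info = logistic_score_info(X, y, beta)
        grad = score - 2.0 * lam * beta
        gnorm = float(np.max(np.abs(grad)))
        trace.append((it, obj, gnorm))
        if gnorm < _GRAD_TOL:
            return beta
        hess = info + 2.0 * lam * np.eye(p)
        step = np.linalg.solve(hess, grad)
        # step-halving: accept only if the penalized objective improves
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_obj = logistic_loglik(X, y, cand) - lam * float(cand @ cand)
            if cand_obj > obj - 1e-14 * abs(obj):
                beta, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            break
    score, _ = logistic_score_info(X, y, beta)
    if float(np.max(np.abs(score - 2.0 * lam * beta))) < _GRAD_TOL:
        return beta
    raise RuntimeError(
        "logistic ridge Newton did not converge; trace (iter, objective, "
        f"grad sup-norm): {trace[-5:]}"
    )
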