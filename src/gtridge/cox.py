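"""Ridge-penalized Cox proportional-hazards machinery.

Covers the partial log-likelihood with Breslow handling of tied event
times, its score and observed information (which feed the asymptotic
globaltest), penalized fitting by damped Newton, the Verweij–van
Houwelingen cross-validated partial likelihood, and the IPCW Brier score
for censored survival predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SurvivalData",
    "cox_loglik",
    "cox_score",
    "ridge_cox_fit",
    "cvpl",
    "brier_score",
]

_MAX_ITER = 50
_GRAD_TOL = 1e-8


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: times t_i ≥ 0 and event indicators
    d_i ∈ {0, 1} (1 = event observed at t_i, 0 = censored at t_i)."""

    times: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.status, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and status must be equal-length vectors")
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        if not np.all(np.isin(d, (0.0, 1.0))):
            raise ValueError("status must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "status", d.astype(int))

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.times[idx], self.status[idx])


def _risk_structure(surv: SurvivalData):
    """Sort ascending by time; return order, per-unique-event-time group
    start indices into the sorted array, and event counts per group."""
    order = np.argsort(surv.times, kind="stable")
    t = surv.times[order]
    d = surv.status[order]
    event_times = np.unique(t[d == 1])
    starts = np.searchsorted(t, event_times, side="left")
    counts = np.array(
        [int(np.sum(d[t == et])) for et in event_times], dtype=int
    )
    return order, t, d, event_times, starts, counts


def cox_loglik(X, surv: SurvivalData, beta) -> float:
    """Breslow partial log-likelihood at ``beta``."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    order, t, d, event_times, starts, counts = _risk_structure(surv)
    eta = X[order] @ beta
    m = float(np.max(eta)) if eta.size else 0.0
    w = np.exp(eta - m)
    s0 = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    for j, start in enumerate(starts):
        ev = (t == event_times[j]) & (d == 1)
        ll += float(eta[ev].sum()) - counts[j] * (math.log(s0[start]) + m)
    return ll


def cox_score(X, surv: SurvivalData, beta0):
    """Score vector and observed information of the partial likelihood.

    Evaluated at ``beta0``; the pair feeds the asymptotic globaltest
    (weights = eigenvalues of the information).
    """
    X = np.asarray(X, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    order, t, d, event_times, starts, counts = _risk_structure(surv)
    Xs = X[order]
    eta = Xs @ beta0
    w = np.exp(eta - np.max(eta))
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    p = X.shape[1]
    score = np.zeros(p)
    info = np.zeros((p, p))
    n = surv.n
    for j, start in enumerate(starts):
        ev = (t == event_times[j]) & (d == 1)
        dj = counts[j]
        xbar = s1[start] / s0[start]
        score += Xs[ev].sum(axis=0) - dj * xbar
        rs = slice(start, n)
        s2 = (Xs[rs] * w[rs, None]).T @ Xs[rs]
        info += dj * (s2 / s0[start] - np.outer(xbar, xbar))
    return score, info


def ridge_cox_fit(X, surv: SurvivalData, lam: float) -> np.ndarray:
    """Maximize the penalized partial likelihood ``ℓ(β) − λ‖β‖²``.

    Breslow ties; damped Newton with step-halving; the penalized score
    has sup-norm below 1e-8 at the returned point.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if surv.n != n:
        raise ValueError("survival data does not match design")
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    if math.isinf(lam):
        return np.zeros(p)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")

    beta = np.zeros(p)
    obj = cox_loglik(X, surv, beta)
    trace = []
    for it in range(_MAX_ITER):
        score, info = cox_score(X, surv, beta)
        grad = score - 2.0 * lam * beta
        gnorm = float(np.max(np.abs(grad)))
        trace.append((it, obj, gnorm))
        if gnorm < _GRAD_TOL:
            return beta
        hess = info + 2.0 * lam * np.eye(p)
        # the information is PSD; the ridge term makes the system PD for lam>0
        if lam == 0.0:
            hess = hess + 1e-10 * np.eye(p)
        step = np.linalg.solve(hess, grad)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_obj = cox_loglik(X, surv, cand) - lam * float(cand @ cand)
            if cand_obj > obj - 1e-14 * abs(obj):
                beta, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            break
    score, _ = cox_score(X, surv, beta)
    if float(np.max(np.abs(score - 2.0 * lam * beta))) < _GRAD_TOL:
        return beta
    raise RuntimeError(
        "Cox ridge Newton did not converge; trace (iter, objective, "
        f"grad sup-norm): {trace[-5:]}"
    )


def cvpl(X, surv: SurvivalData, lam: float, k: int = 5, seed: int = 0) -> float:
    """Cross-validated partial likelihood (Verweij–van Houwelingen).

    ``Σ_folds [ℓ(β̂_{−k}) − ℓ_{−k}(β̂_{−k})]`` where ℓ is the full-data
    partial log-likelihood and ℓ_{−k} the one omitting fold k.  Folds are
    stratified by event status so no training set is event-free; higher
    values indicate better predictive ability.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("need at least two folds")
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(X, surv.status))
        if all(surv.status[tr].sum() >= 1 for tr, _ in folds):
            break
    else:
        raise ValueError("could not build folds with events in every training set")
    total = 0.0
    for train_idx, _ in folds:
        beta_k = ridge_cox_fit(X[train_idx], surv.subset(train_idx), lam)
        total += cox_loglik(X, surv, beta_k) - cox_loglik(
            X[train_idx], surv.subset(train_idx), beta_k
        )
    return total


def _km_censoring(surv: SurvivalData):
    """Kaplan–Meier estimate of the censoring survival function G.

    Returns step-function arrays (times, values) with G right-continuous;
    ``G(t⁻)`` is the value at the last step strictly before t.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(surv.times, event_observed=1 - surv.status)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _step_eval(times, values, t, left: bool = False) -> float:
    side = "left" if left else "right"
    i = np.searchsorted(times, t, side=side) - 1
    return float(values[i]) if i >= 0 else 1.0


def brier_score(surv: SurvivalData, predicted_survival, t_star: float) -> float:
    """IPCW Brier score at horizon ``t_star``.

    Mean squared difference between predicted survival probability
    Ŝ_i(t*) and observed status, weighted by the inverse Kaplan–Meier
    censoring survival: subjects with an observed event before t* enter
    with weight 1/Ĝ(t_i⁻), subjects still at risk past t* with weight
    1/Ĝ(t*), and subjects censored before t* with weight 0.  Lower is
    better.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    if pred.shape != (surv.n,):
        raise ValueError("one predicted survival probability per subject required")
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    if not (surv.times.min() <= t_star <= surv.times.max()):
        raise ValueError("horizon outside the follow-up range")
    gt_times, gt_vals = _km_censoring(surv)
    g_star = _step_eval(gt_times, gt_vals, t_star)
    total = 0.0
    for ti, di, si in zip(surv.times, surv.status, pred):
        if ti <= t_star and di == 1:
            g = _step_eval(gt_times, gt_vals, ti, left=True)
            if g <= 0:
                raise ValueError("weights undefined: censoring KM reaches 0")
            total += si**2 / g
        elif ti > t_star:
            if g_star <= 0:
                raise ValueError("weights undefined: censoring KM reaches 0")
            total += (1.0 - si) ** 2 / g_star
    return total / surv.n
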