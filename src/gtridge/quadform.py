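"""Tail probabilities of quadratic forms in standard normal variables.

Implements Imhof's numerical inversion of the characteristic function of
``Q = Σᵢ wᵢ Zᵢ²`` with arbitrary real weights (the form may be indefinite,
which is exactly what the exact linear-model globaltest null requires):

    P(Q > x) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,

with ``θ(u) = ½ Σᵢ arctan(wᵢ u) − ½ x u`` and
``ρ(u) = Πᵢ (1 + wᵢ² u²)^{1/4}``.

For x = 0 the integrand stops oscillating once the arctans saturate and
adaptive quadrature up to Imhof's truncation bound suffices.  For x ≠ 0
the integrand oscillates forever at frequency |x|/2 and decays only like
``u^{-1-m/2}`` (m weights), so the head is integrated adaptively and the
tail is handled exactly as a Fourier integral: writing
``θ(u) = a(u) − xu/2`` with the bounded phase
``a(u) = ½ Σ arctan(wᵢu) → (π/4) Σ sign(wᵢ)``, the tail splits into
``∫ f(u)·{cos, sin}(|x|u/2) du`` with smooth non-oscillatory amplitudes,
which QUADPACK's QAWF rule integrates to a prescribed absolute accuracy.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import IntegrationWarning, quad

__all__ = ["imhof_tail"]

# analytic truncation-error target for the x = 0 branch
_TRUNC_TOL = 1e-8
# absolute accuracy requested from each quadrature piece
_EPSABS = 1e-9


def _truncation_point(w: np.ndarray) -> float:
    """Upper limit U with Imhof's tail bound 1/(π k U^k Π|wᵢ|^{1/2}) < tol."""
    k = w.size / 2.0
    # work in logs: the product over many small weights under/overflows
    log_u = (-np.log(np.pi * k * _TRUNC_TOL) - 0.5 * np.sum(np.log(np.abs(w)))) / k
    return float(np.exp(min(log_u, 700.0 / max(k, 1.0) + 50.0)))


def _log_rho(w: np.ndarray, u: float) -> float:
    return 0.25 * float(np.sum(np.log1p((w * u) ** 2)))


def imhof_tail(weights, x: float) -> float:
    """Upper-tail probability ``P(Σᵢ wᵢ Zᵢ² > x)``, ``Zᵢ`` iid N(0,1).

    Parameters
    ----------
    weights : array-like
        Real weights of any sign; zero weights contribute nothing and are
        dropped.  All-zero weights raise a ``ValueError``.
    x : float
        Threshold.

    Returns
    -------
    float
        Probability in [0, 1], accurate to about 1e-6 absolute.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0 or not np.all(np.isfinite(w)):
        raise ValueError("weights must be a finite, nonempty vector")
    if not np.isfinite(x):
        raise ValueError("threshold must be finite")
    scale = np.max(np.abs(w))
    if scale == 0.0:
        raise ValueError("degenerate form: all weights are zero")
    w = w / scale
    # weights this far below the largest contribute nothing to the
    # distribution but wreck the truncation bound; drop them
    w = w[np.abs(w) > 1e-13]
    x = x / scale

    # definite forms with the threshold on the wrong side: exact answers
    if x <= 0 and np.all(w > 0):
        return 1.0
    if x >= 0 and np.all(w < 0):
        return 0.0

    def integrand(u: float) -> float:
        if u == 0.0:
            return 0.5 * (float(np.sum(w)) - x)
        theta = 0.5 * float(np.sum(np.arctan(w * u))) - 0.5 * x * u
        log_rho = _log_rho(w, u)
        if log_rho > 700.0:
            return 0.0
        return float(np.sin(theta)) / (u * np.exp(log_rho))

    def _head_integral(end: float) -> float:
        # force log-spaced breakpoints: the arctan transitions happen at
        # u ~ 1/|wᵢ|, which can span many orders of magnitude, and a
        # single global adaptive pass can miss a narrow head entirely
        pts = np.geomspace(min(0.01, end / 10.0), end, 60)[:-1]
        val, _ = quad(
            integrand, 0.0, end, points=pts, limit=2000, epsabs=_EPSABS,
            epsrel=1e-9,
        )
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        if x == 0.0:
            integral = _head_integral(_truncation_point(w))
        else:
            # head: adaptive quadrature over the arctan transition region
            head_end = max(10.0, 10.0 / np.min(np.abs(w)))
            head_end = min(head_end, 1e6)
            integral = _head_integral(head_end)
            # tail: exact Fourier decomposition, sin θ = sin(a(u) + c·u)
            # with bounded phase a and linear frequency c = −x/2
            c = -0.5 * x
            omega = abs(c)
            sgn = 1.0 if c > 0 else -1.0

            def amp_sin_a(u: float) -> float:  # sin a(u) / (u ρ(u))
                a = 0.5 * float(np.sum(np.arctan(w * u)))
                lr = _log_rho(w, u)
                return 0.0 if lr > 700.0 else float(np.sin(a)) / (u * np.exp(lr))

            def amp_cos_a(u: float) -> float:  # cos a(u) / (u ρ(u))
                a = 0.5 * float(np.sum(np.arctan(w * u)))
                lr = _log_rho(w, u)
                return 0.0 if lr > 700.0 else float(np.cos(a)) / (u * np.exp(lr))

            # sin(a + cu) = sin a · cos(ω u) + sign(c) · cos a · sin(ω u)
            part_cos, _ = quad(
                amp_sin_a, head_end, np.inf, weight="cos", wvar=omega,
                epsabs=_EPSABS, limlst=200, limit=500,
            )
            part_sin, _ = quad(
                amp_cos_a, head_end, np.inf, weight="sin", wvar=omega,
                epsabs=_EPSABS, limlst=200, limit=500,
            )
            integral += part_cos + sgn * part_sin

    prob = 0.5 + integral / np.pi
    return float(min(1.0, max(0.0, prob)))
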