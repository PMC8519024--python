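# Methods

## The statistical problem

Ridge regression shrinks the coefficient vector of a (generalized)
linear or Cox model toward zero by maximizing the penalized likelihood
`ℓ(β) − λ‖β‖²`.  Everything depends on the tuning parameter λ, whose
scale is arbitrary and hard to interpret.  This package selects λ by
test inversion: build the 1−α confidence region of β from a hypothesis
test, then pick the *least complex* point of the ridge path that the
test cannot reject,

    λ(α) = sup{ λ ∈ [0, ∞) : β̂_λ ∈ C_α }.

The significance level α replaces λ as the tuning knob.  It has a
direct error-rate interpretation: when the null model β = 0 is true,
the whole path sits inside the region with probability 1−α, so the null
model (λ = ∞) is selected with exactly that probability ("testimation"
type-I control; exact for linear models, asymptotic otherwise).  α =
0.05 gives stringent control; α = 0.5 tracks the effective error rate
of cross-validation and behaves similarly in prediction.

## The globaltest and its null distribution

The region is built from the globaltest, the score test of
H₀: β = β₀ with statistic `S_{β₀} = sᵀs` (squared norm of the score).
It is locally most powerful on average against alternatives spread over
many weak effects — the same regime where ridge shrinkage works well —
and is usable when p ≫ n, where the classical F test does not exist.

For the Gaussian linear model the statistic reduces to the ratio
`S = ‖Xᵀ(y−Xβ₀)‖²/‖y−Xβ₀‖²`, which is scale-free in σ², and
`P(S > c)` equals the probability that the indefinite quadratic form
`εᵀ(XXᵀ − cI)ε` is positive under ε ~ N(0, I): a weighted sum of χ²₁
variables with weights `γᵢ − c` (γᵢ the nonzero eigenvalues of XᵀX)
plus `−c` with multiplicity n − rank.  This null is exact at every n.
For logistic and Cox models the score covariance Σ (observed
information) gives the asymptotic null `Σᵢ ωᵢ χ²₁` with ωᵢ the
eigenvalues of Σ.  No dispersion rescaling is applied to the logistic
or Cox score: both families have fixed dispersion 1, and the region is
driven by the same statistic the test uses.

Tail probabilities of these (possibly indefinite) quadratic forms are
computed by Imhof's characteristic-function inversion.  Numerical
choices:

- weights are rescaled so the largest magnitude is 1; weights below
  1e−13 of the largest are dropped (they contribute nothing but ruin
  the integration range);
- for threshold x = 0 (the exact linear branch) the integrand stops
  oscillating once the arctan terms saturate; it is integrated
  adaptively up to Imhof's analytic truncation bound (target 1e−8)
  with log-spaced forced breakpoints, because the transition scales
  1/|wᵢ| can span many orders of magnitude;
- for x ≠ 0 the integrand oscillates forever at frequency |x|/2; the
  head is integrated adaptively and the tail is evaluated *exactly* as
  a pair of Fourier integrals (QUADPACK QAWF) after factoring the
  bounded arctan phase out of the sine;
- results are clipped to [0, 1]; absolute accuracy is ~1e−6
  (verified against χ² closed forms to ~1e−9 in tests).

Critical values c_α are obtained by root-finding the exact p-value on
(0, γ₁), where it is continuous and strictly decreasing.

## Ridge path and effective complexity

All linear-model quantities run off one thin SVD `X = UΓ^{1/2}Vᵀ` with
singular values below 1e−12 of the largest treated as zero.  The ridge
solution is the spectral form `β̂_λ = Σᵢ γᵢ^{1/2}/(γᵢ+λ) vᵢuᵢᵀy`
(minimum-norm least squares at λ = 0), and the effective model
complexity is `mc(λ) = Σᵢ γᵢ/(γᵢ+λ)`, the trace of the ridge hat map,
which decreases continuously from rank(X) to 0.

λ = ∞ is a first-class sentinel (`numpy.inf`) everywhere, never a large
float: selecting the null model exactly is a central event of the
method and is counted as such.  The default search grid has 100
log-spaced points on `[γ_min·10⁻⁴, γ₁·10⁴]`, which covers the full mc
transition; experiment drivers may use smaller grids (stated below).

No intercept and no standardization are applied by default; both are
available as explicit flags (`center`, `scale`) on the estimators.

## Selection algorithm

Membership of β̂_λ in C_α at level α is equivalent to the p-value of
H₀: β = β̂_λ being ≥ α, and this p-value profile α(λ) is nonincreasing
in λ (from ≈1 near λ = 0 when n > p down to the global-null p-value at
λ = ∞).  The selector therefore:

1. computes the global-null p-value; if ≥ α, returns λ = ∞;
2. otherwise scans the decreasing grid from the top and stops at the
   first point with p ≥ α — scanning from above returns the *largest*
   crossing, matching the supremum definition even if the profile is
   numerically non-monotone (an optional full scan flags
   multi-crossings);
3. refines the bracketing interval by bisection in log λ to a relative
   tolerance of 1e−4.

Boundary ties (p-value exactly α) count as inside the region.  If even
the smallest grid point is rejected (possible when p ≥ n, where the
path cannot saturate the fit), the smallest grid value is returned with
a `no_crossing` diagnostic rather than failing silently.

The F-test (Scheffé) variant tests membership through
`T = ‖Xβ̂ − Xβ̂_λ‖²/(pσ̂²)` against F(p, n−p), with
`σ̂² = ‖y − Xβ̂‖²/(n−p)`; it requires n > p and a full-rank design and
no high-dimensional fallback is offered.

For p = 2 the globaltest region boundary is a conic section classified
by the sign of `δ = det(XᵀXXᵀX − cXᵀX)` (ellipse / parallel lines /
hyperbola), with a zero tolerance of 1e−9 relative to the determinant
scale.  The detectable-region diagnostic reports `cov(γ, r²)` with
`rᵢ² = γᵢ(β−β₀)ᵀVᵢ(β−β₀)/((β−β₀)ᵀXᵀX(β−β₀)+nσ²)`: positive covariance
means the signal loads on large-variance principal components, where
the globaltest is powerful.

## Logistic and Cox fitting

Penalized fits maximize `ℓ(β) − λ‖β‖²` by damped Newton iterations
(step-halving on objective decrease, at most 50 iterations) and require
the penalized gradient sup-norm to fall below 1e−8.  The Cox partial
likelihood uses Breslow tie handling — the simplest consistent choice;
Efron weights, time-varying covariates and stratified baselines are out
of scope.  The cross-validated partial likelihood follows the
Verweij–van Houwelingen construction `Σₖ[ℓ(β̂₋ₖ) − ℓ₋ₖ(β̂₋ₖ)]` with
folds stratified by event status (so no training set is event-free) and
deterministic given the seed.  The Brier score at horizon t* is the
inverse-probability-of-censoring-weighted mean squared difference
between predicted survival probabilities and observed status, with
Kaplan–Meier censoring weights (events before t* weighted by
1/Ĝ(tᵢ⁻), subjects at risk past t* by 1/Ĝ(t*)); it errors out when the
censoring estimate reaches zero at a required time.

## Information criteria and cross-validation baselines

Information criteria minimize `−2ℓ(λ) + penalty(mc, n, p)` over the
grid (∞ sentinel included, ties to the larger λ).  Penalties:
AIC `2mc`; AICc `{2 + 2(mc+1)/(n−mc−1)}mc`; BIC `log(n)·mc`;
mBIC `{log n + 2log(p/4 − 1)}mc`; mBIC2 `{log n + 2log(p/4)}mc −
2log(mc!)` with `mc!` generalized as Γ(mc+1) for continuous mc;
GIC `log(log n)·log(p)·mc`; RIC `2log(p)·mc`.  AICc's penalty is
undefined for mc ≥ n−1; such grid points are skipped.

`ℓ(λ)` is by default the unpenalized Gaussian log-likelihood at β̂_λ
with the profile variance `‖y−Xβ̂_λ‖²/n`.  This choice is deliberate:
with the ridge-penalized likelihood in the criterion the fit term is
dragged down at every finite λ and even AIC collapses onto the null
model almost always, erasing the qualitative distinction between
light- and heavy-penalty criteria (AIC/AICc overfit in high dimensions;
the BIC family underfits) that motivates comparing them.  The penalized
variant is available via `penalized_loglik=True` for sensitivity
analysis.

Cross-validation: k-fold on held-out squared error with seeded folds;
LOOCV through the exact leverage identity
`n⁻¹Σᵢ((yᵢ−ŷᵢ)/(1−hᵢᵢ))²`; GCV `(‖y−Xβ̂_λ‖²/n)/(1−mc/n)²` with grid
points where mc ≥ n skipped with a warning.

## Synthetic data and what it does (not) show

The generators emulate the study conditions rather than any real
dataset:

- designs: `iid` standard normal; `ar1` rows with covariance ρ^|j−k|
  (default ρ = 0.5 — moderate correlation typical of co-expressed
  genes); `spiked` with eigenvalues of XᵀX/n decaying like j^−decay for
  direct spectral control.  The main study dimensions are n = 300,
  p = 50 (low-dimensional) mirroring the sample/feature counts of the
  expression data the method targets;
- responses: `y ~ N(Xβ, σ²I)` with spectral coefficients `β = Vγ^{s/2}`
  — s > 0 aligns signal with strong principal components — and σ²
  calibrated so the signal explains a target fraction
  `r² = βᵀXᵀXβ/(βᵀXᵀXβ + nσ²)` of response variance;
- survival: exponential event times with hazard `rate·exp(xᵀβ)` and
  independent exponential censoring.  This is purely a test harness
  for the Cox layer.

A fixed design is reused across replications (as with real expression
data) and per-replication seeds derive from the scenario seed by a
counter, so single replications are reproducible in isolation.  β is
fixed per (s, r²) cell, deterministic given the design.

Passing tests on these generators demonstrate calibration and the
qualitative power/MSE orderings under Gaussian designs with controlled
spectra; they do not establish behaviour under heavy-tailed expression
measurements, batch structure, or model misspecification, and
design-dependent magnitudes (e.g. exactly how often AIC picks the null
model) will differ on real data.

## Problem sizes used by the shipped experiments

Null-model selection frequencies: n = 300, p = 50, 1000 replications
(the ∞-vs-finite decision needs only the global-null p-value, so this
runs in seconds).  Power ordering across s ∈ {−1, 0, 1}: spiked design,
n = 100, p = 20, r² = 0.1, 200 replications, 40-point grid.  Relative
MSE: spiked design, n = 100, p = 50, s = 1, r² = 0.2, 200 replications.
Calibration checks: 1000 simulated p-values per model family (Cox at
n = 200).  These sizes give Monte-Carlo standard errors of ~0.016 or
less on proportions while keeping the full suite fast.

## Known limitations

- The logistic branch is the only GLM beyond the linear model; the
  tuning layer is family-agnostic through the score interface, so
  adding a family means providing its penalized fit and score/
  information.
- Information criteria and the CV closed forms are implemented for the
  linear model only.
- The F-test selector is undefined for p ≥ n by construction.
- Sparse or out-of-core designs are not supported; everything assumes
  dense matrices that fit in memory.
- When p ≥ n and the response is rejected even at the smallest grid
  penalty, the supremum may not exist on the grid; the result carries a
  `no_crossing` flag instead of an error.
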