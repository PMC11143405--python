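# Methods

## The model

The odd log-logistic generalized exponential (OLLGE) distribution is built
in two stages.  The generalized exponential (GE) baseline on x > 0,
F(x) = (1 − e^{−λx})^α, has scale λ > 0 (units 1/x) and shape α > 0.  The
odd log-logistic transform raises the odds F/(1−F) to a power γ > 0 and
re-normalizes:

    G(x) = F^γ / (F^γ + (1−F)^γ) = logistic( γ · logit F(x) ).

Equivalently, the log-odds of the fitted cdf are γ times the log-odds of
the baseline.  γ = 1 gives GE(α, λ); γ = α = 1 gives Exp(λ).  The density
follows by differentiation,

    g(x) = γ α λ e^{−λx} F₀^{α−1} · [F(1−F)]^{γ−1} / (F^γ + (1−F)^γ)²,

with F₀ = 1 − e^{−λx}.  Near the origin g ~ x^{αγ−1} (reversed-J density
for αγ < 1); in the far tail g ~ const · e^{−γλx}, so γ controls the tail
weight: the moment generating function exists only for t < γλ.  The hazard
tends to γλ, approaching from above when γ > 1 — which is why the mean
residual life is not monotone there even though the GE sub-model with
α > 1 has an increasing hazard (its MRL decreases; both behaviors are
exercised in the tests).

Parameter order everywhere in the code is (λ, α, γ).  Reports label the
parameters explicitly to avoid transposition against tables that use the
(γ, α, λ) order.

## Numerical design of the distribution functions

Forming F^γ and (1−F)^γ directly is hopeless in double precision once F is
within ~1e−16 of 0 or 1, which happens at perfectly ordinary x.  All
functions are therefore assembled from log-space primitives:

* log F₀ = log(1 − e^{−t}) with t = λx is computed by the standard
  `log1mexp` switch (`log(−expm1(−t))` for t < ln 2, `log1p(−exp(−t))`
  beyond); the same helper gives log(1 − F₀^α) from α·log F₀.  Past
  t = 700, where e^{−t} underflows, the complement switches to its tail
  expansion 1 − F ~ α e^{−t}.
* cdf = `expit(γ (log u − log(1−u)))`, sf = `expit(−γ (...))`, so both
  tails are exact to machine precision (sf(500; 1,1,1) = e^{−500}).
* logpdf is built from these logs plus one `logaddexp`; it is never
  log(pdf).  `logpdf(500; 1,1,1)` is exactly −500.
* The quantile function inverts the two stages in closed form:
  u = expit(logit(q)/γ), x = −log(1 − u^{1/α})/λ, again via `log1mexp`.
  At q = 1/2 the tilt is the identity, so the median is γ-free — a useful
  invariant that the tests check.  For extreme q combined with very small
  shape parameters the true quantile lies below the smallest positive
  double and the function returns 0; the round-trip property is therefore
  asserted on the representable region (q in [1e−3, 1−1e−3], shapes ≥ 0.25).
* Sampling is inverse-cdf on uniforms from a seeded `numpy` Generator;
  every stochastic routine takes an explicit seed (int, Generator or
  SeedSequence).

Support conventions: cdf/sf accept x ≤ 0 (0 and 1 respectively); pdf is 0
and logpdf −inf there; hazard raises for x ≤ 0.

## Moments: quadrature is authoritative, the series is an exhibit

Raw moments, the MGF, mean residual life and order-statistic moments are
computed with `scipy.integrate.quad` on segments split at the 5%, 50%, 95%
and 1−1e−6 quantiles.  When αγ < 1 the integrand has an algebraic
singularity at the origin and the quantiles below the median can sit
dozens of decades apart, so the finite segments are integrated under the
substitution s = x^{αγ}, which makes the integrand smooth.  The MGF
integrand is evaluated as exp(t·x + logpdf) to avoid overflowing the bare
exponential before the density damps it.

The classical series development of this family expands the cdf in powers
of u = 1 − e^{−λx}: G = Σ c_k u^k with c obtained by power-series division
of the expansions of u^{αγ} and (1 − u^α)^γ.  Three numerical points
matter:

1. The truncated coefficients are computed in closed form.  The double sum
   Σ_j (−1)^{j+k} C(β,j) C(j,k) collapses, via C(β,j)C(j,k) =
   C(β,k)C(β−k,j−k) and the alternating partial-sum identity, to
   a_k = C(β,k)(−1)^{K−k}C(β−k−1, K−k) at truncation K — no cancelling
   sums, and generalized binomials are evaluated by the falling-factorial
   recurrence (valid at negative integer tops, where Gamma-ratio forms hit
   poles).  The i-sum for (1 − u^α)^γ stops once αi approaches K, where
   the degree-K re-expansion of u^{αi} stops being faithful.
2. The rearrangement is *formal*: for non-integer exponents the function
   has a branch point at u = 0, the coefficients are truncation-dependent,
   and the quotient series can diverge inside (0,1) (for α = γ = 2 the
   denominator has complex zeros at |u| ≈ 0.84).  Where that happens no
   truncation order helps in double precision.  `series_coeffs` therefore
   validates the truncated cdf against the exact cdf on the quantile grid
   [0.01, 0.99] and raises `SeriesTruncationError` on failure;
   `moment_series` compares two truncation orders (K and K−8) and raises
   if they disagree beyond 1e−4 relative.  In practice the series is
   faithful for the γ = 1 family and integer-exponent corners, and fails
   loudly elsewhere; quadrature backs every user-facing value.
3. The inner moment sums S(k, r) = Σ_j (−1)^j C(k,j)/(1+j)^{r+1} cancel
   catastrophically in floats beyond k ≈ 40 and are evaluated exactly with
   `fractions.Fraction` (cached).

Default truncation is K = 40: large enough for 1e−6 cdf accuracy on the
validated corners, small enough that the K-dependent coefficient growth
does not poison the evaluation.

Octile measures use the quantile function directly: Galton skewness
(Q₆+Q₂−2Q₄)/(Q₆−Q₂) and Moors kurtosis (Q₇−Q₅+Q₃−Q₁)/(Q₆−Q₂).  For the
exponential sub-model these have closed forms, 0.26186 and 1.30627, which
the tests pin.  Note that along α = γ = 1..5 at λ = 1 the skewness
decreases monotonically but the kurtosis does not (1.3063, 1.2991, 1.3026,
1.3041, 1.3049): reference tables asserting a monotone decrease do not
follow from the octile definition, whose exponential closed forms they
also contradict, so those columns are not used as fixtures anywhere.

## Estimation

The log-likelihood is Σ logpdf(x_i).  All families (OLLGE, GE, exponential,
log-logistic) share one fitting routine: BFGS on the negative
log-likelihood over log-parameters (positivity for free), run from a
deterministic start grid — shapes in {0.2, 1, 5}, the scale anchored at
1/x̄ (the log-logistic scale at the sample median) — topped up with seeded
log-normal jitter when more starts are requested, followed by a
Nelder–Mead polish of the winning start.  The polish matters: with
numerical gradients BFGS reports "precision loss" at its gradient noise
floor (~1e−5) and can stall visibly short of the optimum on flat ridges.
A candidate counts as converged if BFGS reports success or its final
log-space gradient is below 1e−4.  Ties between starts break toward the
smaller shape estimate.  The exponential family bypasses all of this with
its closed form λ̂ = 1/x̄, −2ℓ̂ = 2n(1 + ln x̄) — which doubles as an
analytic oracle for the numeric path in the tests.

Standard errors come from the observed information: a central-difference
Hessian in log space (step 1e−4·(1+|log θ|)) mapped back to the original
parameterization by the chain rule (the gradient term is included, so the
matrix is meaningful slightly off-optimum).  If the information matrix is
not positive definite the fit is still returned with NaN standard errors.

On the waiting-time data the OLLGE likelihood has an extremely flat ridge
in α: the converged optimum (λ̂, α̂, γ̂) = (0.1706, 44.99, 0.2096) with
−2ℓ̂ = 579.4411 differs from widely tabulated coordinates
(0.1657, 41.571, 0.2159), −2ℓ̂ = 579.4482, by only 0.007 in likelihood.
Coordinates along such a ridge are optimizer-convention artifacts; the
package reports the converged point, and comparisons against tabulated
coordinates should be read as likelihood equivalence.  The flatness also
means SE(α̂) is genuinely large (~43 by the profile curvature).

Goodness of fit: D is the exact sup-distance over order statistics with
the asymptotic Kolmogorov p-value at √n·D (no small-sample correction; R's
ks.test switches to an exact p for small untied samples, which explains
small p discrepancies against some tables).  A* and W* use the common
"adequacy" small-sample modifications A² (1 + 0.75/n + 2.25/n²) and
W² (1 + 0.5/n); reference tables rarely state their exact variant, so these
are a documented convention.  AIC/BIC are always recomputed from −2ℓ̂, k
and n.

## The Monte-Carlo study

`run_simulation` draws B samples of size n by inverse-cdf sampling (one
`SeedSequence` spawns a stream per replicate, so results are reproducible
and scheduling-independent), refits each by ML, and averages θ̂ − θ and
(θ̂ − θ)².  Replicate fits start at the true parameter vector — the
classical recovery-study convention — and escalate to the 9-point reduced
grid on failure; a fit that runs to the parameter-space boundary (the
likelihood can drift along a degenerate ridge when γ is small) counts as
non-convergent.  Non-convergent replicates are replaced with fresh draws
and counted in `n_failed`; the study aborts if more than 20% of attempts
fail.

A caution established while validating this module: at the design point
(λ, α, γ) = (1.5, 1.5, 0.2), n = 300, the inverse Fisher information
(computed two independent ways — numeric Hessian and score outer product,
cross-checked against the exponential closed form) gives an asymptotic
Var(λ̂) of 0.31–0.35.  Reference MSE values near 0.12 for this point are
therefore below the Cramér–Rao bound and cannot be produced by any
consistent ML procedure; they are the signature of an optimizer stopped
early near a truth-valued start.  The same reference tables are consistent
with the bound at the non-degenerate design (0.2, 0.2, 1.5), so the issue
is specific to small γ.  This package reports the converged MLE's
Monte-Carlo MSE (~0.45 at that point) and does not emulate
under-convergence.

Problem sizes used by the shipped runs: the acceptance script uses
B = 1000 replicates at n = 300 for the MSE study; the test suite uses
B = 150 for the same design and B = 150 over n ∈ {50, 150, 300} at the
stable design (0.2, 0.2, 1.0) for the MSE-shrinks-with-n property.

## What the synthetic data does and does not show

All simulation inputs are inverse-cdf draws from the model itself, so the
studies exercise estimator behavior under correct specification:
identifiability, convergence of bias/MSE in n, coverage of the start grid.
They do not probe misspecification, censoring (not supported), ties or
measurement rounding — the bundled real datasets (which contain heavy ties
in the waiting times) are the only check of that kind.  Passing tests
therefore demonstrate internal correctness and faithful reproduction of
the reference analyses, not robustness on arbitrary field data.

## Known limitations

* No censoring, covariates or Bayesian machinery (out of scope).
* The series route is an exhibit of the family's classical algebra, not a
  computational path; it raises rather than silently degrades.
* The MGF domain is enforced as t < λ·min(1, γ) (sufficient and necessary
  for γ ≤ 1; conservative for γ > 1, where existence extends to t < γλ).
* Quantiles at extreme q with very small shape parameters underflow to 0
  (the true values are subnormal); sampling is unaffected at any practical
  sample size.
* For small γ the likelihood can be near-degenerate; fits on such data are
  returned with honest (large) standard errors, and simulation replicates
  that run away are replaced, not truncated.
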