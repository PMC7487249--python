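# Methods

## Model

Each individual grows along a Richards-type curve indexed by its asymptote
`A` (the finite size it approaches):

- anamorphic set: `x = A (1 − exp(−k t))^b`
- polymorphic set: `x = A (1 − exp(−k A^l t))^b`, `l` the asymptote
  exponent (`l = 0` gives the anamorphic set; `l > 0` makes large
  individuals relatively faster).

Assumptions: (1) asymptotes follow a continuous positive distribution;
(2) the curve set is of the form `x = A f(t; A, θ)` with `f` differentiable
in `A` (curve-shape variation is tied to the asymptote — sets whose shape
varies independently of `A`, e.g. a common asymptote with varying rate,
are outside the model); (3) observations are an i.i.d. random sample of
individuals, one (age, size) pair each, without sampling bias or
mortality thinning.

Because every curve is indexed by `A`, the size distribution at fixed age
is the asymptote distribution pushed through a monotone map, and the
likelihood of nonchronological data factorizes as

    LL = Σ ln p(t_i) + Σ ln p(A_i) − Σ ln (dx/dA)_i .

The age term depends only on the age design, so it is dropped; every NLL
this package reports uses that convention. For fixed curve parameters θ
the inner distribution parameters are profiled out by MLE on the
recovered asymptotes `A_i = A(x_i, t_i; θ)`. For the
anamorphic-lognormal model this profile likelihood collapses to ordinary
least squares on `ln x` (checked by a dedicated test), which is why the
guide-curve approach works for anamorphic sets and only for them.

## Asymptote distributions

- **Lognormal(μ, σ)** — closed-form MLE.
- **Generalized gamma (Stacy) (λ, ψ, τ)** — density
  `(τ/Γ(ψ)) λ^{-1} (A/λ)^{ψτ−1} exp(−(A/λ)^τ)`; contains the gamma
  (τ = 1), Weibull (ψ = 1) and, as ψ → ∞, the lognormal.

The generalized gamma MLE exploits the fact that for fixed τ the
transformed sample `w = A^τ` is gamma distributed, so shape and scale
profile out via the standard digamma equation (Newton iterations from the
usual closed-form start); the full MLE is then a one-dimensional bounded
search over τ (coarse log-grid plus Brent refinement). This is exact,
deterministic, and fast enough to sit inside the outer global search; it
reproduces `scipy.stats.gengamma.fit` log-likelihoods to < 0.05 nats in
tests.

The likelihood surface is ridged along the lognormal limit: ψ → ∞ forces
τ → 0 and λ → 0 at matched moments. Search boxes λ ∈ [10⁻⁶, 10³],
ψ ∈ [10⁻³, 10⁶], τ ∈ [0.1, 10] truncate that ridge, so on exactly
lognormal data the reachable generalized-gamma likelihood sits slightly
(≲ a few tenths of a nat at n ≈ 100) below the lognormal one. Nesting
comparisons in the tests carry a corresponding small slack.

## Inversion and Jacobian

Recovering `A` from an observation inverts `x = A f(t; A, θ)`:

- `l = 0`: closed form `A = x / (1 − e^{−kt})^b`.
- `l > 0`: the map is strictly increasing in `A`; the bracket `[x,
  max(2x, a_ref)]` is doubled (capped at 10⁶·x) until the sign changes,
  then bisection plus three Newton steps with the analytic Jacobian
  reach relative tolerance 10⁻¹⁰. The array path performs the bisection
  vectorized over all observations; a scalar Brent reference
  (`invert_asymptote_brent`) cross-checks it in tests.
- `l < 0`: the map can fold. A 64-point log-spaced scan of the bracket
  counts sign changes: none is an inversion failure (no curve of the set
  reaches that size), more than one raises an ambiguity error rather than
  silently picking a root.

Inside optimization, any inversion failure or degenerate asymptote sample
(zero ln-variance, where the profile likelihood is unbounded) poisons the
whole candidate θ with a +inf sentinel — partial likelihoods over the
invertible subset would not be comparable across candidates.

All formulas are evaluated in log space (`expm1`/`log1p` branches) so that
saturation fractions near 0 or 1 and rates spanning eleven decades stay
accurate.

## Outer optimization

The outer search over θ uses a particle swarm with constriction
coefficients (w = 0.729, c1 = c2 = 1.49445), velocity clamped to half the
box width, boundary reflection, and a final bounded Nelder–Mead polish
from the incumbent; it is deterministic given its seed. Default budget is
40 particles × 300 iterations; the simulation experiments and tests use
smaller budgets (12–20 particles, 40–100 iterations), which the polish
step makes sufficient for these 2–3-dimensional problems — the
acceptance-grade recovery results below were produced at those budgets.

The search runs in reparameterized coordinates: `log10 k'` with
`k' = k · a_ref^l` on [−12, −1], `b` on [0.01, 5], and (polymorphic only)
`l` on [−10, 10]. The reference asymptote `a_ref` (default 25, roughly an
average asymptote for the tree-height applications the defaults target)
keeps the effective rate at a typical asymptote inside a fixed range
whatever `l` is; the natural rate is recovered as `k = k' / a_ref^l`.
Published parameter tables for these models report the rate in the `k'`
convention for polymorphic fits — the package's reference parameter sets
(`reference_models()`) interpret them accordingly, and `FitResult` reports
both `k` and `k_prime`.

The generalized-gamma inner fit is warm-started from the previous
evaluation's optimum (the warm τ joins the grid), which only affects
speed: the profile is re-solved exactly at every evaluation.

## Model comparison and uncertainty

- AIC = 2·NLL + 2·K with K = 4 (AL), 5 (AG, PL), 6 (PG).
- Likelihood-ratio tests for the nested pairs AL–AG, AL–PL, AG–PG, PL–PG
  (df = 1) and AL–PG (df = 2), refused for AG–PL (not nested in either
  direction). The plain χ² reference distribution is used even though
  boundary cases (ψ at its cap) violate the usual regularity conditions;
  this matches standard practice for these comparisons and is noted here
  as a caveat.
- Bootstrap: case resampling with replacement (default B = 1001),
  percentile (Efron) 2.5/97.5 intervals. Basic-vs-percentile is a genuine
  open choice; percentile was chosen as the simplest reading of an
  "empirical bootstrap" and is isolated in `bootstrap_ci` if a basic
  variant is ever wanted. Replicate swarms are seeded with the point
  estimate, which stabilizes refits without biasing percentiles.

## Synthetic data and what the checks mean

`synthetic_data.generate` draws ages uniformly over the model's age range
(11–110 years for the cypress reference models, 11–118 for larch — the
ranges of the surveys behind the reference parameter sets, whose age
distributions were roughly uniform), asymptotes from the asymptote law,
and computes sizes deterministically from the curve set. There is **no
residual noise term**: the model attributes all size variation at an age
to the asymptote distribution, and the generator emulates exactly that.
Real data additionally carry measurement error, site covariates, sampling
bias and mortality thinning, none of which are modelled — passing
recovery tests therefore show internal consistency of the estimator, not
robustness to those features.

Experiments:

- `parameter_recovery` — simulate-and-refit, one row of estimates per
  replicate. With the larch AL truth, n = 200 and 100 replicates, the
  median estimates land within ~3% of the generating μ, k, b, σ
  (recomputed by `scripts/acceptance.py`).
- `reproductivity_experiment` — per replicate, fit blind to the truth and
  record the growth curves through the 2.5th/50th/97.5th percentile
  asymptotes on an age grid; aggregate pointwise medians and 2.5/97.5
  percentile bands. Ages are redrawn each replicate (the fixed-design
  alternative would shrink the bands slightly). With a proper estimator
  the bands cover the true curves and narrow as n doubles; with an
  anamorphic estimator fitted to polymorphic truth, the bands for the
  tail-percentile curves miss the true curves at old ages — the low curve
  underestimated and the high curve overestimated — and more data does
  not repair the bias. The acceptance suite runs this at 101 replicates
  of n = 100; the published-scale version (1,001 replicates) is the
  default of the `reproduce` CLI command.

## Numerical and design notes

- Degenerate inputs: identical ln-asymptotes raise a structured
  degenerate-sample error (fit paths) or return the +inf sentinel
  (optimization paths).
- Duplicate (t, x) rows are ordinary i.i.d. observations; no special
  treatment.
- ψ is capped at 10⁶ during fitting: beyond the cap the family is
  numerically indistinguishable from its lognormal limit but Γ-function
  terms overflow.
- Exact zeros of `1 − exp(−u)` cannot occur for positive arguments, but
  `u` may overflow for extreme search candidates (`l` near ±10); these
  evaluate to well-defined limits under `np.errstate` guards and, where
  the likelihood is genuinely undefined, to the +inf sentinel.
- Seeds: every stochastic entry point (sampling, swarm, bootstrap,
  experiments) takes an explicit integer seed; replicate seeds are
  spawned from a `SeedSequence` so replicates are independent but
  reproducible.

## Known limitations

- Type-B curve sets (common asymptote, shape varying independently of it)
  are outside the model class by construction.
- Covariates, random effects, measurement error and mortality correction
  are not implemented.
- The χ² reference for boundary-parameter LRTs is approximate (above).
- For `l < 0` the size–asymptote map can fold; such observations are
  reported as ambiguous rather than resolved.
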