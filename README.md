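# polygrowth

Maximum-likelihood estimation of **growth curve sets** — anamorphic and
polymorphic — from **nonchronological** size–age data: one-time
observations `(t_i, x_i)` of many individuals, with no per-individual
growth history.

## The problem

Collections of growth curves usually vary in an orderly way: each
individual follows a Richards-type curve towards its own asymptote `A`,
and curve shape may change gradually with `A`. Two families of curve sets
are supported:

- **anamorphic** — one standard curve scaled by the asymptote,
  `x = A (1 − e^{−kt})^b`; after dividing by `A` all curves coincide;
- **polymorphic** — the rate grows with the asymptote,
  `x = A (1 − e^{−k A^l t})^b`, so standardized curves differ
  (`l = 0` recovers the anamorphic set).

With only nonchronological data the classical guide-curve regression is
valid solely for anamorphic sets. But the curve set itself determines how
the population of asymptotes maps into the observable size distribution at
each age: with asymptotes `A ~ p(A)` and the monotone map
`A ↦ x = A f(t; A, θ)`, the change of variables gives

    p(x | t) = p(A(x, t)) · (dx/dA)^{-1}

and the log-likelihood of the data (dropping the constant age term)

    LL(θ) = Σ_i ln p̂(A_i) − Σ_i ln (dx/dA)_i ,

where `A_i` is recovered by inverting the curve through `(x_i, t_i)` and
`p̂` is the maximum-likelihood fit of the asymptote distribution
(lognormal or generalized gamma) to the recovered `A_i` — a profile
likelihood over the distribution parameters at each curve parameter
vector θ. This stays well-defined for polymorphic sets, where the Jacobian
`dx/dA = (1−E)^b + k l b t A^l E (1−E)^{b−1}` (with `E = e^{−k A^l t}`)
carries the extra information that the curve shape varies with `A`.

Four instance models are provided — **AL**, **AG**, **PL**, **PG**
(anamorphic/polymorphic × lognormal/generalized-gamma, with 4/5/5/6 free
parameters) — together with AIC, likelihood-ratio tests between the nested
pairs (AG–PL is refused as non-nested), case-resampling bootstrap
confidence intervals, percentile growth curves, and a simulation harness
that checks whether an estimator reproduces a known generating model.

## Worked example

```python
import numpy as np
import polygrowth as pg

# a known polymorphic generating model (cypress tree heights, metres)
truth = pg.reference_models()["cypress_PG"]

# 100 nonchronological observations: uniform ages, sizes on the curves
data = pg.generate(truth, n=100, seed=5)

settings = pg.PsoSettings(n_particles=12, n_iters=40, seed=3)
for name in ("AL", "PL"):
    fit = pg.fit_model(data, pg.ModelSpec.from_name(name), settings)
    print(name, f"NLL={fit.nll:.3f} AIC={fit.aic:.3f}")
```

prints

```
AL NLL=244.929 AIC=497.858
PL NLL=234.265 AIC=478.531
```

The polymorphic fit improves the log-likelihood by ~10.7 nats at the cost
of one extra parameter (AIC 478.5 vs 497.9): the anamorphic model cannot
represent the shrinking spread of sizes at old ages in data generated by a
polymorphic set, and the likelihood — through the Jacobian term — detects
exactly that. A likelihood-ratio test makes it formal:

```python
lrt = pg.likelihood_ratio_test(
    pg.fit_model(data, pg.ModelSpec.from_name("AL"), settings),
    pg.fit_model(data, pg.ModelSpec.from_name("PL"), settings))
print(lrt)   # LRT AL vs PL: chi2 = 21.33, df = 1, p = 0.0000***
```

A command-line surface wraps the same operations
(`polygrowth fit|compare|bootstrap|simulate|reproduce`, each with a
mandatory `--seed` and an output directory of CSV/JSON artifacts).

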