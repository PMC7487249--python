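"""Model fitting, comparison and uncertainty for growth curve sets.

Ties the profile likelihood to the swarm optimizer and adds the standard
model-selection machinery: AIC, likelihood-ratio tests between nested
instance models, case-resampling (empirical) bootstrap confidence
intervals, and percentile growth curves (the curves through the median and
tail quantiles of the fitted asymptote distribution).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import chi2 as chi2_dist

from .distributions import AsymptoteDistribution
from .growth_models import GrowthParams, ObservationSet, evaluate
from .likelihood import LikelihoodValue, ModelSpec, profile_negloglik
from .pso import NoFeasiblePointError, PsoResult, PsoSettings, pso_minimize

__all__ = [
    "FitResult",
    "LrtResult",
    "BootstrapResult",
    "FitFailureError",
    "NotNestedError",
    "aic",
    "fit_model",
    "likelihood_ratio_test",
    "bootstrap_ci",
    "percentile_curves",
    "significance_stars",
]

logger = logging.getLogger(__name__)

#: nested (reduced, full) pairs among the four instance models, with the
#: degrees of freedom of the likelihood-ratio test
NESTED_PAIRS = {
    ("AL", "AG"): 1,
    ("AL", "PL"): 1,
    ("AG", "PG"): 1,
    ("PL", "PG"): 1,
    ("AL", "PG"): 2,
}


class FitFailureError(RuntimeError):
    """The outer search found no feasible curve parameters."""


class NotNestedError(ValueError):
    """Likelihood-ratio test requested for a non-nested model pair."""


def aic(nll: float, k_params: int) -> float:
    """Akaike information criterion: ``2 * NLL + 2 * K``."""
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    return 2.0 * float(nll) + 2.0 * int(k_params)


@dataclass
class FitResult:
    """A fitted instance model.

    ``nll`` excludes the constant age term, matching the likelihood
    convention used throughout; ``k_params`` counts all free parameters
    (curve and distribution), and ``aic = 2 nll + 2 k_params``.
    """

    spec: ModelSpec
    theta: GrowthParams
    dist: AsymptoteDistribution
    nll: float
    k_params: int
    aic: float
    trace: NDArray | None = None
    n_obs: int = 0

    def params_dict(self) -> dict[str, float]:
        out = {"k": self.theta.k, "b": self.theta.b}
        if self.spec.curve_family == "polymorphic":
            # k' = k * a_ref**l is the bounded, display-friendly rate
            out["l"] = self.theta.l
            out["k_prime"] = self.theta.k_prime
        out.update(self.dist.params_dict())
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "params": self.params_dict(),
            "a_ref": self.spec.a_ref,
            "nll": self.nll,
            "k_params": self.k_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test between two nested fitted models."""

    chi2: float
    df: int
    p: float
    reduced: str
    full: str

    def __str__(self) -> str:
        return (f"LRT {self.reduced} vs {self.full}: chi2 = {self.chi2:.2f}, "
                f"df = {self.df}, p = {self.p:.4f}{significance_stars(self.p)}")


@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs from case resampling.

    ``estimates`` holds one row per successful replicate (columns are the
    free parameters); ``ci`` maps parameter -> (2.5th, 97.5th) percentile.
    """

    ci: dict[str, tuple[float, float]]
    estimates: pd.DataFrame
    B: int
    n_failures: int
    point: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (lo, hi) in self.ci.items():
            rows.append({"param": name, "estimate": self.point.get(name),
                         "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star convention: * 10%, ** 1%, *** 0.1% (blank: not significant)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def fit_model(
    data: ObservationSet,
    spec: ModelSpec,
    settings: PsoSettings | None = None,
    init_theta: GrowthParams | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one instance model.

    Runs the particle swarm over the curve parameters in the search
    coordinates (log10 k', b, and l when polymorphic); the asymptote
    distribution is profiled out inside the objective.  The generalized
    gamma inner fit is warm-started from the previous evaluation's optimum,
    which only affects speed, not the converged value.
    """
    settings = settings or PsoSettings()
    if len(data) < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} observations to fit "
            f"{spec.name}, got {len(data)}"
        )
    warm: list[AsymptoteDistribution | None] = [None]

    def objective(vec: NDArray) -> float:
        theta = spec.theta_from_vector(vec)
        lv = profile_negloglik(theta, data, spec, dist_warm_start=warm[0])
        if lv.ok and spec.dist_family == "gengamma":
            warm[0] = lv.dist
        return lv.nll

    init = spec.vector_from_theta(init_theta) if init_theta is not None else None
    try:
        res: PsoResult = pso_minimize(
            objective, spec.search_bounds(), settings, init_guess=init
        )
    except NoFeasiblePointError as err:
        raise FitFailureError(
            f"no feasible curve parameters for model {spec.name}: {err}"
        ) from err

    theta = spec.theta_from_vector(res.x)
    # final clean evaluation (no warm start) at the optimum
    lv: LikelihoodValue = profile_negloglik(theta, data, spec,
                                            dist_warm_start=warm[0])
    if not lv.ok:
        raise FitFailureError(
            f"model {spec.name}: optimum infeasible on re-evaluation "
            f"({lv.failure})"
        )
    k = spec.n_params
    return FitResult(spec=spec, theta=theta, dist=lv.dist, nll=lv.nll,
                     k_params=k, aic=aic(lv.nll, k), trace=res.trace,
                     n_obs=len(data))


def likelihood_ratio_test(fit_reduced: FitResult, fit_full: FitResult) -> LrtResult:
    """Likelihood-ratio test between nested instance models.

    The statistic is ``2 (NLL_reduced - NLL_full)`` referred to a
    chi-squared distribution with ``K_full - K_reduced`` degrees of
    freedom.  Only the nested pairs AL-AG, AL-PL, AG-PG, PL-PG and AL-PG
    are admissible; AG and PL are not nested in either direction (one frees
    the distribution, the other the curve set) and the test is refused.
    """
    pair = (fit_reduced.spec.name, fit_full.spec.name)
    if pair not in NESTED_PAIRS:
        raise NotNestedError(
            f"models {pair[0]} and {pair[1]} are not nested (reduced, full); "
            "the likelihood-ratio test is only defined for "
            + ", ".join("-".join(p) for p in NESTED_PAIRS)
        )
    df = fit_full.k_params - fit_reduced.k_params
    chi2 = 2.0 * (fit_reduced.nll - fit_full.nll)
    if chi2 < 0:
        logger.warning(
            "negative LRT statistic (%.4g) for %s vs %s: the full model's "
            "optimizer fell short; treating as 0", chi2, *pair
        )
        chi2 = max(chi2, 0.0)
    p = float(chi2_dist.sf(chi2, df))
    return LrtResult(chi2=chi2, df=df, p=p, reduced=pair[0], full=pair[1])


def bootstrap_ci(
    data: ObservationSet,
    spec: ModelSpec,
    B: int = 1001,
    seed: int = 0,
    settings: PsoSettings | None = None,
    point_fit: FitResult | None = None,
) -> BootstrapResult:
    """Empirical-bootstrap percentile confidence intervals.

    Draws ``B`` case resamples (rows with replacement, size n), refits the
    model on each, and reports per-parameter 2.5th/97.5th percentiles of
    the replicate estimates.  Replicates whose fit fails are logged,
    excluded and counted.  The point estimate seeds each replicate's swarm,
    which stabilizes and speeds the refits without biasing percentiles.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    settings = settings or PsoSettings()
    if point_fit is None:
        point_fit = fit_model(data, spec, settings)
    n = len(data)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * B)
    rng = np.random.default_rng(child_seeds[0])

    rows = []
    n_fail = 0
    for rep in range(B):
        idx = rng.integers(0, n, size=n)
        resample = ObservationSet(ages=data.ages[idx], sizes=data.sizes[idx])
        rep_settings = PsoSettings(
            n_particles=settings.n_particles, n_iters=settings.n_iters,
            w=settings.w, c1=settings.c1, c2=settings.c2,
            velocity_clamp=settings.velocity_clamp,
            seed=int(child_seeds[B + rep] % (2**31)), tol=settings.tol,
            patience=settings.patience, polish=settings.polish,
        )
        try:
            fit = fit_model(resample, spec, rep_settings,
                            init_theta=point_fit.theta)
        except (FitFailureError, ValueError) as err:
            logger.info("bootstrap replicate %d failed: %s", rep, err)
            n_fail += 1
            continue
        rows.append(fit.params_dict())
    if not rows:
        raise FitFailureError(
            f"all {B} bootstrap replicates failed for model {spec.name}"
        )
    est = pd.DataFrame(rows)
    ci = {c: (float(np.percentile(est[c], 2.5)),
              float(np.percentile(est[c], 97.5))) for c in est.columns}
    return BootstrapResult(ci=ci, estimates=est, B=B, n_failures=n_fail,
                           point=point_fit.params_dict())


def percentile_curves(
    fit_or_parts,
    quantiles,
    ages,
) -> pd.DataFrame:
    """Growth curves through quantiles of the fitted asymptote distribution.

    For each quantile q the trajectory is ``x(t) = f(t; A_q, theta)`` with
    ``A_q = quantile(dist, q)``.  Accepts either a :class:`FitResult` or a
    ``(theta, dist)`` pair; returns a DataFrame indexed by age with one
    column per quantile.
    """
    if isinstance(fit_or_parts, FitResult):
        theta, dist = fit_or_parts.theta, fit_or_parts.dist
    else:
        theta, dist = fit_or_parts
    ages = np.asarray(ages, dtype=float)
    out = {}
    for q in quantiles:
        A_q = dist.quantile(float(q))
        out[float(q)] = evaluate(theta, A_q, ages)
    return pd.DataFrame(out, index=pd.Index(ages, name="age"))
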