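"""Profile likelihood of a growth curve set given nonchronological data.

The observable at age ``t`` is the size ``x`` of a randomly sampled
individual.  Because each individual's whole curve is indexed by its
asymptote ``A``, the size distribution at any fixed age is the asymptote
distribution pushed through the monotone map ``A -> A f(t; A, theta)``:

    p(x | t) = p(A(x, t)) / (dx/dA),

and the log-likelihood of n observations is

    LL = sum_i ln p(t_i) + sum_i ln p(A_i) - sum_i ln (dx/dA)_i.

The age term is a constant of the data (ages carry no information about the
curve set) and is excluded from every likelihood value reported by this
package.  For fixed curve parameters theta, the asymptote-distribution
parameters that maximize LL are the MLE on the recovered asymptotes
{A_i}, so the outer optimizer only ever searches over theta: the profile
likelihood computed by :func:`profile_negloglik`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .distributions import (
    AsymptoteDistribution,
    DegenerateSampleError,
    fit_mle,
)
from .growth_models import (
    GrowthParams,
    InversionError,
    ObservationSet,
    dx_dA,
    invert_asymptote,
)

__all__ = [
    "ModelSpec",
    "LikelihoodValue",
    "DEFAULT_BOUNDS",
    "profile_negloglik",
    "conditional_size_density",
    "conditional_size_cdf",
]

logger = logging.getLogger(__name__)

#: outer search box, in the reparameterized coordinates actually searched:
#: log10 of k' (k' spans 11 decades), b, and l
DEFAULT_BOUNDS = {
    "log10_k_prime": (-12.0, -1.0),
    "b": (0.01, 5.0),
    "l": (-10.0, 10.0),
}

MODEL_NAMES = ("AL", "AG", "PL", "PG")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four instance models: curve family x asymptote family.

    ``AL``/``AG`` are anamorphic (l fixed at 0) with lognormal / generalized
    gamma asymptotes; ``PL``/``PG`` are the polymorphic counterparts with
    the asymptote exponent l free.  Free-parameter counts are 4, 5, 5 and 6.
    """

    curve_family: str  # "anamorphic" | "polymorphic"
    dist_family: str   # "lognormal" | "gengamma"
    a_ref: float = 25.0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.curve_family not in ("anamorphic", "polymorphic"):
            raise ValueError(f"unknown curve family {self.curve_family!r}")
        if self.dist_family not in ("lognormal", "gengamma"):
            raise ValueError(f"unknown distribution family {self.dist_family!r}")
        if not self.a_ref > 0:
            raise ValueError("a_ref must be > 0")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")

    @classmethod
    def from_name(cls, name: str, a_ref: float = 25.0, **kw) -> "ModelSpec":
        name = name.upper()
        if name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}, got {name!r}")
        return cls(
            curve_family="anamorphic" if name[0] == "A" else "polymorphic",
            dist_family="lognormal" if name[1] == "L" else "gengamma",
            a_ref=a_ref, **kw,
        )

    @property
    def name(self) -> str:
        return (("A" if self.curve_family == "anamorphic" else "P")
                + ("L" if self.dist_family == "lognormal" else "G"))

    @property
    def n_params(self) -> int:
        """Free parameters: (k, b) + l if polymorphic + distribution params."""
        n = 2 + (0 if self.curve_family == "anamorphic" else 1)
        n += 2 if self.dist_family == "lognormal" else 3
        return n

    @property
    def search_dims(self) -> list[str]:
        """Coordinates of the outer (theta) search, in order."""
        dims = ["log10_k_prime", "b"]
        if self.curve_family == "polymorphic":
            dims.append("l")
        return dims

    def theta_from_vector(self, vec: NDArray) -> GrowthParams:
        """Map a search vector to natural-scale curve parameters."""
        k_prime = 10.0 ** float(vec[0])
        b = float(vec[1])
        l = float(vec[2]) if self.curve_family == "polymorphic" else 0.0
        return GrowthParams.from_k_prime(k_prime, b, l, a_ref=self.a_ref)

    def vector_from_theta(self, theta: GrowthParams) -> NDArray:
        vec = [np.log10(theta.k_prime), theta.b]
        if self.curve_family == "polymorphic":
            vec.append(theta.l)
        return np.asarray(vec, dtype=float)

    def search_bounds(self) -> NDArray:
        return np.asarray([self.bounds[d] for d in self.search_dims])


@dataclass
class LikelihoodValue:
    """Profile likelihood evaluation at one theta.

    ``nll`` is the negative log-likelihood in nats, excluding the constant
    age term.  On failure (inversion impossible, degenerate asymptote
    spread) ``nll`` is +inf and ``failure`` names the cause; the remaining
    fields are then None.  Optimizers treat +inf as an infeasible candidate.
    """

    nll: float
    dist: AsymptoteDistribution | None = None
    asymptotes: NDArray | None = None
    jacobians: NDArray | None = None
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return np.isfinite(self.nll)


def profile_negloglik(
    theta: GrowthParams,
    data: ObservationSet,
    spec: ModelSpec,
    dist_warm_start: AsymptoteDistribution | None = None,
) -> LikelihoodValue:
    """Negative profile log-likelihood of theta on nonchronological data.

    Recovers each observation's asymptote by inverting the curve set, fits
    the asymptote distribution of ``spec.dist_family`` to the recovered
    values by ML, and returns

        NLL = -( sum_i ln p_hat(A_i) - sum_i ln (dx/dA)_i ).

    Failures return a +inf sentinel instead of raising so that an outer
    global optimizer can discard the candidate and continue; a partial
    likelihood over the invertible subset would not be comparable across
    candidates, so one bad observation poisons the whole theta.
    """
    try:
        A = invert_asymptote(theta, data.sizes, data.ages)
    except InversionError as err:
        logger.debug("inversion failed at theta=%s: %s", theta, err)
        return LikelihoodValue(nll=np.inf, failure=f"inversion: {err}")
    J = np.asarray(dx_dA(theta, A, data.ages))
    if not np.all(np.isfinite(J)) or np.any(J <= 0):
        return LikelihoodValue(nll=np.inf, failure="nonpositive jacobian")
    try:
        dist, ll_dist = fit_mle(A, spec.dist_family, x0=dist_warm_start)
    except DegenerateSampleError as err:
        logger.debug("degenerate asymptotes at theta=%s: %s", theta, err)
        return LikelihoodValue(nll=np.inf, failure=f"degenerate: {err}")
    nll = -(ll_dist - float(np.sum(np.log(J))))
    if not np.isfinite(nll):
        return LikelihoodValue(nll=np.inf, failure="non-finite likelihood")
    return LikelihoodValue(nll=nll, dist=dist, asymptotes=A, jacobians=J)


def conditional_size_density(
    theta: GrowthParams,
    dist: AsymptoteDistribution,
    t: float,
    x,
):
    """Density of size at a fixed age implied by the curve set and asymptote law.

    ``p(x | t) = p(A(x, t)) / (dx/dA)`` evaluated at the asymptote of the
    curve through (x, t).  Vectorized over ``x``; points where no curve of
    the set passes through (x, t) get density 0.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x_arr)
    for i, xi in enumerate(x_arr):
        try:
            A = invert_asymptote(theta, float(xi), float(t))
        except InversionError:
            logger.debug("no curve through (x=%g, t=%g); density 0", xi, t)
            continue
        out[i] = np.exp(dist.logpdf(A)) / dx_dA(theta, A, float(t))
    return out[0] if np.ndim(x) == 0 else out


def conditional_size_cdf(
    theta: GrowthParams,
    dist: AsymptoteDistribution,
    t: float,
    x: float,
) -> float:
    """CDF of size at fixed age: the asymptote CDF at A(x, t) (monotone map)."""
    A = invert_asymptote(theta, float(x), float(t))
    return float(dist.cdf(A))
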