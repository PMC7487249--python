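"""Asymptote distributions: lognormal and generalized gamma (Stacy).

The nonchronological likelihood treats each individual's asymptote ``A`` as
a draw from a continuous positive distribution.  Two families are supported:

* lognormal with parameters (mu, sigma) of ln A;
* the three-parameter generalized gamma with density

      pdf(A | lam, psi, tau)
          = tau / Gamma(psi) * (1/lam) * (A/lam)^(psi*tau - 1)
            * exp(-(A/lam)^tau),

  which contains the gamma distribution (tau = 1), the Weibull distribution
  (psi = 1) and, in the psi -> infinity limit, the lognormal distribution.

Each family provides log density, sampling, quantiles, CDF and
maximum-likelihood fitting.  Log densities go through ``gammaln`` so that
extreme shape parameters (psi up to 1e6, where the family hugs its
lognormal limit) stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import minimize_scalar
from scipy.special import (
    digamma,
    gammainc,
    gammaincinv,
    gammaln,
    ndtr,
    polygamma,
)

__all__ = [
    "Lognormal",
    "GenGamma",
    "AsymptoteDistribution",
    "DegenerateSampleError",
    "GENGAMMA_BOUNDS",
    "fit_mle",
    "fit_lognormal",
    "fit_gengamma",
]

#: default fitting/search box for the generalized gamma, (low, high) pairs
GENGAMMA_BOUNDS = {
    "lam": (1e-6, 1e3),
    "psi": (1e-3, 1e6),
    "tau": (0.1, 10.0),
}


class DegenerateSampleError(ValueError):
    """Samples with (near-)zero spread: the MLE degenerates to a point mass."""


def _check_positive(A: ArrayLike) -> NDArray[np.float64]:
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("asymptote values must be strictly positive")
    return A


def _check_prob(q: ArrayLike) -> NDArray[np.float64]:
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return q


@dataclass(frozen=True)
class Lognormal:
    """Lognormal asymptote distribution: ln A ~ Normal(mu, sigma^2)."""

    mu: float
    sigma: float

    family = "lognormal"
    n_params = 2

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def logpdf(self, A: ArrayLike):
        A = _check_positive(A)
        z = (np.log(A) - self.mu) / self.sigma
        out = -np.log(A) - np.log(self.sigma) - 0.5 * np.log(2 * np.pi) \
            - 0.5 * z * z
        return out.item() if out.ndim == 0 else out

    def pdf(self, A: ArrayLike):
        return np.exp(self.logpdf(A))

    def cdf(self, A: ArrayLike):
        A = _check_positive(A)
        out = ndtr((np.log(A) - self.mu) / self.sigma)
        return out.item() if np.ndim(out) == 0 else out

    def quantile(self, q: ArrayLike):
        q = _check_prob(q)
        from scipy.special import ndtri
        out = np.exp(self.mu + self.sigma * ndtri(q))
        return out.item() if np.ndim(out) == 0 else out

    def sample(self, n: int, rng: np.random.Generator | int) -> NDArray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return np.exp(rng.normal(self.mu, self.sigma, size=int(n)))

    def params_dict(self) -> dict[str, float]:
        return {"mu": self.mu, "sigma": self.sigma}


@dataclass(frozen=True)
class GenGamma:
    """Generalized gamma (Stacy) asymptote distribution.

    Parameterized so that ``A = lam * G**(1/tau)`` with ``G ~ Gamma(psi)``:
    lam is the scale, psi and tau the two shape parameters.
    """

    lam: float
    psi: float
    tau: float

    family = "gengamma"
    n_params = 3

    def __post_init__(self) -> None:
        for name in ("lam", "psi", "tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def logpdf(self, A: ArrayLike):
        A = _check_positive(A)
        y = np.log(A) - np.log(self.lam)
        out = (np.log(self.tau) - gammaln(self.psi) - np.log(self.lam)
               + (self.psi * self.tau - 1.0) * y - np.exp(self.tau * y))
        return out.item() if out.ndim == 0 else out

    def pdf(self, A: ArrayLike):
        return np.exp(self.logpdf(A))

    def cdf(self, A: ArrayLike):
        A = _check_positive(A)
        out = gammainc(self.psi, (A / self.lam) ** self.tau)
        return out.item() if np.ndim(out) == 0 else out

    def quantile(self, q: ArrayLike):
        q = _check_prob(q)
        g = gammaincinv(self.psi, q)
        out = self.lam * g ** (1.0 / self.tau)
        return out.item() if np.ndim(out) == 0 else out

    def sample(self, n: int, rng: np.random.Generator | int) -> NDArray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        g = rng.gamma(self.psi, size=int(n))
        return self.lam * g ** (1.0 / self.tau)

    def params_dict(self) -> dict[str, float]:
        return {"lam": self.lam, "psi": self.psi, "tau": self.tau}


AsymptoteDistribution = Union[Lognormal, GenGamma]


def fit_lognormal(samples: ArrayLike) -> tuple[Lognormal, float]:
    """Closed-form lognormal MLE: mu = mean(ln A), sigma^2 = MLE variance.

    Returns the fitted distribution and its maximized log-likelihood.
    Raises :class:`DegenerateSampleError` when the ln-samples have
    (numerically) zero variance, where the likelihood is unbounded.
    """
    A = _check_positive(samples)
    if A.size < 2:
        raise ValueError("need at least 2 samples to fit a lognormal")
    logs = np.log(A)
    mu = float(np.mean(logs))
    var = float(np.mean((logs - mu) ** 2))
    if var <= 1e-14 * max(1.0, mu * mu):
        raise DegenerateSampleError(
            "ln-samples have zero variance; sigma-hat = 0 gives an unbounded "
            "likelihood"
        )
    dist = Lognormal(mu=mu, sigma=float(np.sqrt(var)))
    ll = float(np.sum(dist.logpdf(A)))
    return dist, ll


def _gamma_shape_mle(s: float, psi_lo: float, psi_hi: float) -> float:
    """Solve ln(psi) - digamma(psi) = s for the gamma shape MLE.

    ``s = ln(mean w) - mean(ln w) >= 0`` by Jensen; the solution decreases
    in s.  Uses the standard closed-form approximation as a start, then a
    few Newton steps, clipped into [psi_lo, psi_hi].
    """
    if s <= 0:
        return psi_hi
    psi = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    psi = min(max(psi, psi_lo), psi_hi)
    for _ in range(6):
        f = np.log(psi) - digamma(psi) - s
        fp = 1.0 / psi - polygamma(1, psi)
        step = f / fp
        psi_new = psi - step
        if not np.isfinite(psi_new) or psi_new <= 0:
            psi_new = psi / 2.0 if f < 0 else psi * 2.0
        psi = min(max(psi_new, psi_lo), psi_hi)
        if abs(step) < 1e-10 * psi:
            break
    return psi


def _profile_ll_tau(tau: float, A: NDArray, logs: NDArray,
                    sum_logs: float, bounds: dict) -> tuple[float, float, float]:
    """Max log-likelihood over (lam, psi) at fixed tau, with the maximizers.

    For fixed tau, ``w = A**tau`` is Gamma(psi) with scale lam**tau, so the
    inner problem is a plain gamma MLE: psi solves ln psi - digamma(psi) =
    ln(mean w) - mean(ln w) and the scale is mean(w)/psi.  When psi hits
    its box edge (the lognormal ridge), the scale is re-profiled at the
    clipped psi.  Returns (ll, lam, psi).
    """
    n = A.size
    logw = tau * logs
    shift = float(np.max(logw))        # overflow guard for A**tau at tau ~ 10
    wbar = float(np.mean(np.exp(logw - shift)))
    log_wbar = np.log(wbar) + shift
    s = log_wbar - tau * sum_logs / n
    psi = _gamma_shape_mle(s, bounds["psi"][0], bounds["psi"][1])
    log_scale = log_wbar - np.log(psi)
    lam = np.exp(log_scale / tau)
    lam = min(max(lam, bounds["lam"][0]), bounds["lam"][1])
    log_scale = tau * np.log(lam)
    # gamma LL on w plus the Jacobian of w = A**tau; a clipped lam far from
    # the unconstrained optimum can push the exponent past overflow, in
    # which case the LL is effectively -inf
    expo = log_wbar - log_scale
    if expo > 700.0:
        return -np.inf, float(lam), float(psi)
    ll = (n * (-gammaln(psi) - psi * log_scale)
          + (psi - 1.0) * tau * sum_logs
          - n * np.exp(expo)
          + n * np.log(tau) + (tau - 1.0) * sum_logs)
    return float(ll), float(lam), float(psi)


def fit_gengamma(
    samples: ArrayLike,
    x0: GenGamma | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_grid: int = 12,
) -> tuple[GenGamma, float]:
    """Generalized gamma MLE via an exact profile over tau.

    For fixed tau the transformed samples ``w = A**tau`` follow a plain
    gamma law, whose shape and scale MLEs are (semi-)closed form; the full
    three-parameter MLE therefore reduces to a one-dimensional bounded
    search over tau.  A coarse log-spaced grid locates the best basin
    (guarding against multimodality) and Brent's method refines it.  The
    likelihood surface is ridged along the psi -> infinity lognormal limit;
    psi is capped at its box edge (1e6 by default) and the remaining
    parameters re-profiled there, which approximates the limit without
    overflow.  ``x0`` (a warm start from an enclosing optimization) merely
    adds its tau to the grid.
    """
    A = _check_positive(samples)
    if A.size < 3:
        raise ValueError("need at least 3 samples to fit a generalized gamma")
    logs = np.log(A)
    if float(np.var(logs)) <= 1e-14:
        raise DegenerateSampleError(
            "ln-samples have zero variance; the gengamma MLE degenerates"
        )
    b = bounds or GENGAMMA_BOUNDS
    sum_logs = float(np.sum(logs))
    t_lo, t_hi = b["tau"]

    taus = list(np.exp(np.linspace(np.log(t_lo), np.log(t_hi), n_grid)))
    if x0 is not None and t_lo < x0.tau < t_hi:
        taus.append(x0.tau)
    ll_grid = [_profile_ll_tau(t, A, logs, sum_logs, b)[0] for t in taus]
    order = np.argsort(taus)
    taus_s = np.asarray(taus)[order]
    ll_s = np.asarray(ll_grid)[order]
    i = int(np.argmax(ll_s))
    lo = taus_s[max(i - 1, 0)]
    hi = taus_s[min(i + 1, len(taus_s) - 1)]

    neg = lambda t: -_profile_ll_tau(float(t), A, logs, sum_logs, b)[0]
    # tau located to ~1e-5: the profile LL is flat at second order around
    # its maximum, so tighter tolerances only cost inner-loop time
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    tau = float(res.x) if -res.fun >= ll_s[i] else float(taus_s[i])
    ll, lam, psi = _profile_ll_tau(tau, A, logs, sum_logs, b)
    return GenGamma(lam=lam, psi=psi, tau=tau), ll


def fit_mle(samples: ArrayLike, family: str,
            x0: AsymptoteDistribution | None = None
            ) -> tuple[AsymptoteDistribution, float]:
    """Fit an asymptote distribution of the given family by ML.

    Returns ``(distribution, log-likelihood at the optimum)``.
    """
    if family == "lognormal":
        return fit_lognormal(samples)
    if family == "gengamma":
        return fit_gengamma(samples, x0=x0 if isinstance(x0, GenGamma) else None)
    raise ValueError(f"unknown family {family!r}; use 'lognormal' or 'gengamma'")
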