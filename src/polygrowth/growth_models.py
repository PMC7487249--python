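"""Anamorphic and polymorphic Richards growth curve sets.

A growth curve set assigns one Richards-type curve to each individual through
its asymptote ``A``.  The anamorphic set scales a single standard curve,

    x = A * (1 - exp(-k t))^b,

while the polymorphic set lets the rate depend on the asymptote through a
power law, ``k_i = k * A_i^l``:

    x = A * (1 - exp(-k A^l t))^b.

``l = 0`` recovers the anamorphic set.  The three operations needed by the
nonchronological likelihood live here: forward evaluation, the derivative of
size with respect to the asymptote at fixed age (the Jacobian of the change
of variables), and the inversion from an observed (size, age) pair back to
the asymptote of the curve passing through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import brentq

__all__ = [
    "GrowthParams",
    "ObservationSet",
    "InversionError",
    "AmbiguousInversionError",
    "evaluate",
    "dx_dA",
    "invert_asymptote",
]

#: arguments of exp(-u) below -_EXP_CLIP are flushed to exp -> 0
_EXP_CLIP = 700.0


class InversionError(ValueError):
    """No asymptote solves x = A f(t; A, theta) within the search bracket."""

    def __init__(self, msg: str, x: float | None = None, t: float | None = None):
        super().__init__(msg)
        self.x = x
        self.t = t


class AmbiguousInversionError(InversionError):
    """Multiple asymptotes solve x = A f(t; A, theta) (possible when l < 0)."""


@dataclass(frozen=True)
class GrowthParams:
    """Shape parameters of a Richards growth curve set.

    Parameters
    ----------
    k : float
        Rate parameter (per year), > 0, on the natural scale.  Optimizers
        search the reparameterized rate ``k' = k * a_ref**l`` so that the
        effective rate at a typical asymptote stays in a fixed range; the
        two are related by ``k = k' / a_ref**l``.
    b : float
        Shape exponent, > 0.
    l : float
        Asymptote exponent.  ``l = 0`` gives the anamorphic set; positive
        values make larger individuals grow relatively faster.
    a_ref : float
        Reference asymptote used by the ``k'`` reparameterization (default
        25, a rough average asymptote for the tree-height applications the
        defaults target).
    """

    k: float
    b: float
    l: float = 0.0
    a_ref: float = 25.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if not self.a_ref > 0:
            raise ValueError(f"a_ref must be > 0, got {self.a_ref}")

    @property
    def k_prime(self) -> float:
        """Reparameterized rate ``k' = k * a_ref**l``."""
        return self.k * self.a_ref**self.l

    @classmethod
    def from_k_prime(cls, k_prime: float, b: float, l: float = 0.0,
                     a_ref: float = 25.0) -> "GrowthParams":
        """Build from the reparameterized rate: ``k = k' / a_ref**l``."""
        return cls(k=k_prime / a_ref**l, b=b, l=l, a_ref=a_ref)

    @property
    def is_anamorphic(self) -> bool:
        return self.l == 0.0


@dataclass(frozen=True)
class ObservationSet:
    """Nonchronological observations: one (age, size) pair per individual."""

    ages: NDArray[np.float64]
    sizes: NDArray[np.float64]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        sizes = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "sizes", sizes)
        if ages.ndim != 1 or sizes.ndim != 1:
            raise ValueError("ages and sizes must be 1-D arrays")
        if ages.shape != sizes.shape:
            raise ValueError(
                f"ages and sizes differ in length: {ages.size} vs {sizes.size}"
            )
        if ages.size < 1:
            raise ValueError("need at least one observation")
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(sizes)):
            raise ValueError("ages and sizes must be finite")
        if np.any(ages <= 0) or np.any(sizes <= 0):
            raise ValueError("ages and sizes must be strictly positive")

    def __len__(self) -> int:
        return int(self.ages.size)


def _log1mexp(u: ArrayLike) -> NDArray[np.float64]:
    """log(1 - exp(-u)) for u > 0, numerically stable at both ends."""
    u = np.asarray(u, dtype=float)
    # u small: 1 - exp(-u) ~ u, expm1 keeps accuracy; u large: log1p branch
    return np.where(
        u < np.log(2.0),
        np.log(-np.expm1(-np.minimum(u, 1.0))),
        np.log1p(-np.exp(-np.clip(u, np.log(2.0), _EXP_CLIP))),
    )


def _check_domain(A: ArrayLike, t: ArrayLike) -> tuple[NDArray, NDArray]:
    A = np.asarray(A, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(A <= 0):
        raise ValueError("asymptote A must be strictly positive")
    if np.any(t <= 0):
        raise ValueError("age t must be strictly positive")
    return A, t


def evaluate(params: GrowthParams, A: ArrayLike, t: ArrayLike):
    """Size at age ``t`` on the curve with asymptote ``A``.

    Computes ``x = A (1 - exp(-k A^l t))^b`` in log space so that tiny
    saturation fractions (k A^l t >> 1 or << 1) stay accurate.  Broadcasts
    over ``A`` and ``t``; returns a scalar for scalar inputs.
    """
    A, t = _check_domain(A, t)
    with np.errstate(over="ignore"):  # extreme l during global search
        u = params.k * A**params.l * t
        logx = np.log(A) + params.b * _log1mexp(u)
        x = np.exp(logx)
    return x.item() if x.ndim == 0 else x


def dx_dA(params: GrowthParams, A: ArrayLike, t: ArrayLike):
    """Derivative of size with respect to the asymptote at fixed age.

    With ``E = exp(-k A^l t)`` this is

        dx/dA = (1 - E)^b + k l b t A^l E (1 - E)^(b-1),

    which collapses to ``(1 - exp(-k t))^b`` for the anamorphic set
    (``l = 0``), independent of ``A``.
    """
    A, t = _check_domain(A, t)
    with np.errstate(over="ignore", invalid="ignore"):
        u = params.k * A**params.l * t
        log_one_mE = _log1mexp(u)
        base = np.exp(params.b * log_one_mE)          # (1 - E)^b
        if params.l == 0.0:
            out = base * np.ones_like(u)
        else:
            # second term: k l b t A^l E (1-E)^(b-1) = l b u E (1-E)^(b-1)
            logE = -np.minimum(u, _EXP_CLIP)
            ratio = np.exp(logE - log_one_mE)          # E / (1 - E)
            out = base * (1.0 + params.l * params.b * u * ratio)
    return out.item() if out.ndim == 0 else out


def _bracket_upper(params: GrowthParams, x: NDArray, t: NDArray,
                   max_factor: float = 1e6) -> NDArray:
    """Expand the upper bracket edge geometrically until g(A) = x - f changes sign.

    ``A = x`` is always a valid lower edge because any curve lies strictly
    below its asymptote, so g(x) > 0.
    """
    upper = np.maximum(2.0 * x, params.a_ref)
    g = x - evaluate(params, upper, t)
    pending = g > 0
    # doubling from 2x reaches the 1e6*x cap within ~20 steps; the fixed
    # iteration cap also guards against rounding at the cap itself
    for _ in range(int(np.ceil(np.log2(max_factor))) + 2):
        if not np.any(pending):
            break
        upper = np.where(pending, np.minimum(upper * 2.0, max_factor * x), upper)
        g = np.where(pending, x - evaluate(params, upper, t), g)
        pending = pending & (g > 0) & (upper < max_factor * x)
    if np.any(g > 0):  # never bracketed even at the cap
        i = int(np.argmax(g > 0))
        raise InversionError(
            "no sign change while bracketing the asymptote "
            f"(x={x.flat[i]:.6g}, t={t.flat[i]:.6g}); the curve set may not "
            "reach this size at this age",
            x=float(x.flat[i]), t=float(t.flat[i]),
        )
    return upper


def _scan_bracket_nonmonotone(params: GrowthParams, x: NDArray, t: NDArray,
                              max_factor: float = 1e6, n_scan: int = 64
                              ) -> tuple[NDArray, NDArray]:
    """Bracket the root of g(A) = x - A f(t; A) when the map may fold (l < 0).

    The size is not monotone in A here, so endpoint signs cannot be
    trusted: a coarse log-spaced scan of [x, max_factor * x] counts sign
    changes per observation.  Exactly one change gives the bracket; none
    means the curve set never reaches this size (inversion failure); more
    than one means the observation is consistent with several asymptotes
    (ambiguity).
    """
    lo = np.log(x)
    hi = np.log(max_factor * x)
    frac = np.linspace(0.0, 1.0, n_scan)
    grid = np.exp(lo[..., None] + (hi - lo)[..., None] * frac)
    g = x[..., None] - evaluate(params, grid, t[..., None])
    neg = g <= 0
    flip = np.diff(neg, axis=-1)
    n_flips = np.sum(flip, axis=-1)
    if np.any(n_flips == 0):
        i = int(np.argmax(n_flips == 0))
        raise InversionError(
            "no sign change while bracketing the asymptote "
            f"(x={x.flat[i]:.6g}, t={t.flat[i]:.6g}); the curve set may not "
            "reach this size at this age",
            x=float(x.flat[i]), t=float(t.flat[i]),
        )
    if np.any(n_flips > 1):
        i = int(np.argmax(n_flips > 1))
        raise AmbiguousInversionError(
            "multiple candidate asymptotes in the bracket "
            f"(x={x.flat[i]:.6g}, t={t.flat[i]:.6g}, l={params.l}); the "
            "curve set is non-monotone in A here",
            x=float(x.flat[i]), t=float(t.flat[i]),
        )
    first = np.argmax(flip, axis=-1)
    take = lambda idx: np.take_along_axis(grid, idx[..., None], -1)[..., 0]
    return take(first), take(first + 1)


def invert_asymptote(params: GrowthParams, x: ArrayLike, t: ArrayLike,
                     rtol: float = 1e-10):
    """Asymptote of the curve passing through the observation (x, t).

    For the anamorphic set the inverse is the closed form
    ``A = x / (1 - exp(-k t))^b``.  Otherwise the root of
    ``g(A) = x - A f(t; A, theta)`` is found by bracketed bisection followed
    by Newton polish, to relative tolerance ``rtol``; broadcasts over x and
    t.  When ``l < 0`` the map A -> x can be non-monotone, so a coarse scan
    first checks the bracket for multiple roots and raises
    :class:`AmbiguousInversionError` if any are seen.
    """
    x, t = _check_domain(x, t)  # same positivity constraints apply
    scalar = x.ndim == 0 and np.asarray(t).ndim == 0
    x, t = np.broadcast_arrays(np.atleast_1d(x), np.atleast_1d(t))
    x = x.astype(float)
    t = t.astype(float)

    if params.l == 0.0:
        logf = params.b * _log1mexp(params.k * t)
        A = np.exp(np.log(x) - logf)
        return A.item() if scalar else A

    if params.l < 0:
        lo, hi = _scan_bracket_nonmonotone(params, x, t)
        upper = hi
    else:
        upper = _bracket_upper(params, x, t)
        lo = x.copy()
        hi = upper.copy()
    # bisection: halve until the interval is below rtol * midpoint
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = x - evaluate(params, mid, t)
        lo = np.where(g > 0, mid, lo)
        hi = np.where(g > 0, hi, mid)
        if np.all(hi - lo <= rtol * mid):
            break
    A = 0.5 * (lo + hi)
    # Newton polish using the analytic Jacobian (dg/dA = -dx/dA)
    for _ in range(3):
        g = x - evaluate(params, A, t)
        J = dx_dA(params, A, t)
        step = np.where(J > 0, g / np.where(J > 0, J, 1.0), 0.0)
        A = np.clip(A + step, x, upper)
    return A.item() if scalar else A


def invert_asymptote_brent(params: GrowthParams, x: float, t: float,
                           rtol: float = 1e-12) -> float:
    """Scalar inversion via Brent's method (reference route for cross-checks)."""
    x = float(x)
    t = float(t)
    if params.l == 0.0:
        return invert_asymptote(params, x, t)
    xv = np.asarray([x])
    tv = np.asarray([t])
    if params.l < 0:
        lo_v, hi_v = _scan_bracket_nonmonotone(params, xv, tv)
        lo, hi = float(lo_v[0]), float(hi_v[0])
    else:
        lo, hi = x, float(_bracket_upper(params, xv, tv)[0])
    return brentq(lambda A: x - evaluate(params, A, t), lo, hi, rtol=rtol)
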