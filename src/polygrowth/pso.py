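"""Bounded global optimization by particle swarm, with a local polish.

The profile likelihood over the curve parameters is a low-dimensional but
non-convex surface (the rate spans eleven decades and the asymptote
exponent trades off against it), so a population-based global search is
used for the outer problem.  The swarm uses the standard constriction
coefficients (w = 0.729, c1 = c2 = 1.49445), velocity clamping at half the
box width and reflection at the boundaries, and the incumbent is polished
with a bounded Nelder-Mead simplex at the end.  Objectives may return +inf
to mark infeasible points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize

__all__ = ["PsoSettings", "PsoResult", "NoFeasiblePointError", "pso_minimize"]


class NoFeasiblePointError(RuntimeError):
    """Every objective evaluation returned +inf."""


@dataclass(frozen=True)
class PsoSettings:
    """Swarm hyperparameters.

    Defaults are the well-studied constriction settings; the budget
    (particles x iterations) is the main cost knob and is deliberately
    modest for the 2-3 dimensional searches this package performs.
    """

    n_particles: int = 40
    n_iters: int = 300
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    velocity_clamp: float = 0.5
    seed: int = 0
    tol: float = 0.0          # stop early when incumbent stalls by < tol ...
    patience: int = 50        # ... for this many iterations (tol=0 disables)
    polish: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iters < 1:
            raise ValueError("n_particles and n_iters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("inertia w must lie in (0, 1)")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")


@dataclass
class PsoResult:
    x: NDArray
    fun: float
    trace: NDArray          # best-so-far objective per iteration
    n_evals: int
    polished: bool


def _reflect(pos: NDArray, vel: NDArray, lo: NDArray, hi: NDArray):
    """Reflect positions (and flip velocities) at the box boundaries."""
    for _ in range(4):  # a particle can overshoot both walls at high velocity
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            break
        pos = np.where(below, 2 * lo - pos, pos)
        pos = np.where(above, 2 * hi - pos, pos)
        vel = np.where(below | above, -vel, vel)
    np.clip(pos, lo, hi, out=pos)
    return pos, vel


def pso_minimize(
    objective: Callable[[NDArray], float],
    bounds,
    settings: PsoSettings | None = None,
    init_guess: NDArray | None = None,
) -> PsoResult:
    """Minimize a bounded objective with a particle swarm.

    Parameters
    ----------
    objective : callable
        Maps a point in the box to a float; +inf marks infeasible points.
    bounds : array-like of shape (d, 2)
        Finite (low, high) per dimension.
    settings : PsoSettings
        Hyperparameters; ``settings.seed`` makes the run deterministic.
    init_guess : array, optional
        A point seeded as the first particle (e.g. a previous fit when
        bootstrapping), clipped into the box.

    Returns
    -------
    PsoResult with the best position, value, per-iteration incumbent trace
    and evaluation count.  Raises :class:`NoFeasiblePointError` if no
    evaluation was ever finite.
    """
    settings = settings or PsoSettings()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or not np.all(lo < hi):
        raise ValueError("bounds must be finite with lo < hi")
    d = bounds.shape[0]
    width = hi - lo
    vmax = settings.velocity_clamp * width

    rng = np.random.default_rng(settings.seed)
    n = settings.n_particles
    pos = lo + rng.uniform(size=(n, d)) * width
    if init_guess is not None:
        pos[0] = np.clip(np.asarray(init_guess, dtype=float), lo, hi)
    vel = rng.uniform(-1, 1, size=(n, d)) * vmax

    def f(p: NDArray) -> float:
        v = float(objective(p))
        return v if np.isfinite(v) else np.inf

    fvals = np.array([f(p) for p in pos])
    n_evals = n
    pbest = pos.copy()
    pbest_f = fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    trace = np.empty(settings.n_iters)
    stall = 0
    for it in range(settings.n_iters):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        vel = (settings.w * vel
               + settings.c1 * r1 * (pbest - pos)
               + settings.c2 * r2 * (gbest - pos))
        np.clip(vel, -vmax, vmax, out=vel)
        pos, vel = _reflect(pos + vel, vel, lo, hi)
        fvals = np.array([f(p) for p in pos])
        n_evals += n
        improved = fvals < pbest_f
        pbest[improved] = pos[improved]
        pbest_f[improved] = fvals[improved]
        g = int(np.argmin(pbest_f))
        prev = gbest_f
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace[it] = gbest_f
        if settings.tol > 0:
            stall = stall + 1 if prev - gbest_f < settings.tol else 0
            if stall >= settings.patience:
                trace = trace[: it + 1]
                break

    if not np.isfinite(gbest_f):
        raise NoFeasiblePointError(
            "all objective evaluations were infeasible (+inf)"
        )

    polished = False
    if settings.polish:
        def fb(p: NDArray) -> float:
            if np.any(p < lo) or np.any(p > hi):
                return np.inf
            return f(p)

        res = minimize(
            fb, gbest, method="Nelder-Mead",
            options={"maxiter": 200 * d, "xatol": 1e-9, "fatol": 1e-10},
        )
        n_evals += res.nfev
        if np.isfinite(res.fun) and res.fun <= gbest_f:
            gbest, gbest_f = np.clip(res.x, lo, hi), float(res.fun)
            polished = True

    return PsoResult(x=gbest, fun=gbest_f, trace=trace,
                     n_evals=n_evals, polished=polished)
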