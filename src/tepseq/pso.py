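"""Global-best particle-swarm optimization.

Each particle carries a position x and velocity v inside a bounded box.
Per iteration the velocity update mixes inertia, a cognitive pull toward
the particle's own best position, and a social pull toward the swarm's
best position:

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with r1, r2 uniform per dimension.  Velocities are clamped to a fraction
of the box width and positions to the box.  Coefficients default to the
constriction-style values w = 0.72, c1 = c2 = 1.49.  The optimizer
minimizes; callers wanting a maximum pass the negated objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class PSOConfig:
    n_particles: int = 20
    n_iterations: int = 10
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    velocity_clamp: float = 0.2  # fraction of box width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("need at least 1 particle and 1 iteration")


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    trace: list[float] = field(default_factory=list)  # global best per iteration
    n_evaluations: int = 0


def minimize_pso(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: PSOConfig,
    seeds: Sequence[np.ndarray] | None = None,
) -> PSOResult:
    """Minimize ``objective`` over a box with a global-best particle swarm.

    ``seeds`` optionally pins the first particles to given positions (e.g.
    a grid-search optimum), guaranteeing the result is never worse than
    the best seed.  The global-best trace is non-increasing by
    construction.  A non-finite objective value counts as the worst
    possible evaluation (the particle keeps moving).
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("PSO bounds must be finite")
    width = hi - lo
    d = lo.size
    n = config.n_particles

    x = lo + rng.random((n, d)) * width
    if seeds:
        for i, s in enumerate(seeds[:n]):
            x[i] = np.clip(np.asarray(s, dtype=float), lo, hi)
    vmax = config.velocity_clamp * width
    v = (rng.random((n, d)) * 2.0 - 1.0) * vmax

    def safe_eval(xi: np.ndarray) -> float:
        val = objective(xi)
        return float(val) if np.isfinite(val) else np.inf

    f = np.array([safe_eval(xi) for xi in x])
    evals = n
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    for _ in range(config.n_iterations - 1):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = np.array([safe_eval(xi) for xi in x])
        evals += n
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)

    return PSOResult(best_x=gbest_x, best_f=gbest_f, trace=trace, n_evaluations=evals)
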