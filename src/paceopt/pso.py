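"""Global-best particle swarm optimization over a bounded box.

Standard constricted PSO (inertia 0.729, cognitive and social coefficients
1.49) with positions clipped to the box and velocities clamped to half the
box width.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["particle_swarm"]


def particle_swarm(
    objective: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    swarm_size: int,
    iterations: int,
    seed: int,
    inertia: float = 0.729,
    cognitive: float = 1.49,
    social: float = 1.49,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float], int]:
    """Minimize ``objective`` over the box [lower, upper].

    Returns ``(best_x, best_f, history, n_evaluations, archive)`` where
    ``history`` holds the best objective found up to and including each
    iteration (iteration 0 is the evaluation of the initial swarm) and is
    non-increasing by construction, and ``archive`` is the final
    per-particle best ``(positions, values)`` pair — useful for seeding a
    local refinement from several distinct basins.

    ``init`` optionally seeds the position of the first particle (e.g. a
    nominal parameter vector known to be feasible).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(lower >= upper):
        raise ValueError("need lower < upper elementwise")
    if iterations < 1 or swarm_size < 2:
        raise ValueError("need at least 1 iteration and 2 particles")

    rng = np.random.default_rng(seed)
    dim = lower.size
    width = upper - lower
    pos = lower + width * rng.random((swarm_size, dim))
    if init is not None:
        pos[0] = np.clip(np.asarray(init, dtype=float), lower, upper)
    vel = 0.1 * width * (2.0 * rng.random((swarm_size, dim)) - 1.0)
    vmax = 0.5 * width

    pbest = pos.copy()
    pbest_f = np.array([objective(x) for x in pos])
    n_eval = swarm_size
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    history = [gbest_f]

    for _ in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        vel = (
            inertia * vel
            + cognitive * r1 * (pbest - pos)
            + social * r2 * (gbest[None, :] - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lower, upper)
        for i in range(swarm_size):
            fi = objective(pos[i])
            n_eval += 1
            if fi < pbest_f[i]:
                pbest[i] = pos[i]
                pbest_f[i] = fi
                if fi < gbest_f:
                    gbest, gbest_f = pos[i].copy(), float(fi)
        history.append(gbest_f)

    return gbest, gbest_f, history, n_eval, (pbest, pbest_f)
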