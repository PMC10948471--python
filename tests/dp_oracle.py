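"""Independent brute-force oracle: value-iteration dynamic programming.

Solves the toy minimum-time problem (flat track, constant aerobic power,
no rate limits on force) by backward induction on a dense state grid with
the force as a freely chosen control per step.  Completely independent of
the collocation solver: explicit midpoint stepping in distance and
bilinear interpolation of the value function.  The state is (w, e) with
w = v^2, in which both the dynamics (dw/ds = 2f - 2 sqrt(w)/tau) and the
value function are smooth enough for bilinear interpolation.
"""

import numpy as np


def dp_min_time(
    distance: float,
    tau: float,
    f_max: float,
    sigma: float,
    e0: float,
    v_start: float = 1.0,
    ds: float = 0.25,
    n_w: int = 220,
    n_e: int = 140,
    n_f: int = 81,
    v_max: float = 12.0,
) -> float:
    """Minimal time to cover ``distance`` starting at ``v_start`` with a
    full anaerobic store, for dynamics dv/ds = (f - v/tau)/v and
    de/ds = (sigma - f v)/v with e kept non-negative."""
    w_lo, w_hi = 0.25, v_max**2
    w_grid = np.linspace(w_lo, w_hi, n_w)
    e_grid = np.linspace(0.0, e0, n_e)
    f_grid = np.linspace(0.0, f_max, n_f)
    n_steps = int(round(distance / ds))

    W = w_grid[:, None, None]  # (n_w, 1, 1)
    E = e_grid[None, :, None]  # (1, n_e, 1)
    F = f_grid[None, None, :]  # (1, 1, n_f)
    J = np.zeros((n_w, n_e))
    INF = 1e9

    dw_grid = w_grid[1] - w_grid[0]
    de_grid = e_grid[1] - e_grid[0]

    def interp(J, w, e):
        iw = np.clip((w - w_lo) / dw_grid, 0, n_w - 1 - 1e-9)
        ie = np.clip(e / de_grid, 0, n_e - 1 - 1e-9)
        i0 = iw.astype(int)
        j0 = ie.astype(int)
        fw = iw - i0
        fe = ie - j0
        return (
            J[i0, j0] * (1 - fw) * (1 - fe)
            + J[i0 + 1, j0] * fw * (1 - fe)
            + J[i0, j0 + 1] * (1 - fw) * fe
            + J[i0 + 1, j0 + 1] * fw * fe
        )

    # precompute the state-control step (independent of J)
    v = np.sqrt(W)
    dw1 = 2.0 * F - 2.0 * v / tau
    de1 = sigma / v - F
    wm = np.clip(W + 0.5 * ds * dw1, w_lo, w_hi)
    vm = np.sqrt(wm)
    dw2 = 2.0 * F - 2.0 * vm / tau
    de2 = sigma / vm - F
    w_next = W + ds * dw2
    e_next = E + ds * de2
    dt = ds / vm  # midpoint quadrature of 1/v
    feasible = (e_next >= 0.0) & (w_next >= w_lo) & (w_next <= w_hi)
    w_next_c = np.clip(w_next, w_lo, w_hi)
    wb = np.broadcast_to(w_next_c, (n_w, e_grid.size, f_grid.size))
    eb = np.broadcast_to(e_next, wb.shape)

    for _ in range(n_steps):
        cost = np.where(feasible, dt + interp(J, wb, eb), INF)
        J = cost.min(axis=2)

    return float(
        interp(J, np.array([v_start**2]), np.array([e0]))[0]
    )
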