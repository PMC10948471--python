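"""Athlete parameter identification from observed races.

The observation is either an official split table (cumulative times every
100 m, as published for championship races) or a 10 Hz instantaneous
velocity trace from in-stadium athlete tracking.  Identification searches a
bounded parameter box with particle swarm optimization; each candidate is
scored by solving the minimum-time optimal race at those parameters and
measuring the discrepancy against the observation — the model prediction
is always the athlete's optimal race, not a free-form force profile.

Solves for nearby parameter sets are warm-started from the best solution
found so far, which keeps the swarm affordable; the whole procedure is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .energetics import AthleteParams
from .ocp import RaceSolution, solve_min_time
from .pso import particle_swarm
from .synthetic import VelocityTrace
from .track import TrackGeometry

__all__ = [
    "ObservedRace",
    "SearchSpace",
    "IdentificationResult",
    "fit_objective",
    "identify_parameters",
    "default_search_space",
    "nominal_athlete",
    "INFEASIBLE_PENALTY",
]

#: objective value returned for parameter sets whose race cannot be solved
INFEASIBLE_PENALTY = 1e6


def default_search_space(event: int = 1500) -> "SearchSpace":
    """Physiological identification box for a world-class athlete.

    Bounds cover the elite range: anaerobic stores up to the high values
    this model family attributes to champions, peak aerobic power between
    ~57 and ~88 ml/kg/min of VO2, and phase thresholds that put the
    aerobic plateau onset within the first half of anaerobic depletion.
    Total force, and motor-control rates are fixed: neither is
    identifiable from 100 m splits.
    """
    if event == 1500:
        return SearchSpace(
            bounds={
                "e0": (2500.0, 9000.0),
                "f_M": (8.0, 13.0),
                "tau": (0.8, 1.5),
                "sigma_max": (20.0, 31.0),
                "sigma_f": (14.0, 31.0),
                "sigma_r": (2.0, 20.0),
                "gamma1": (0.03, 0.45),
                "gamma2": (0.5, 0.97),
            },
            fixed={"f_tot": 14.0, "r_inc": 2.5, "r_dec": 2.5},
        )
    if event == 400:
        return SearchSpace(
            bounds={
                "e0": (1500.0, 5000.0),
                "f_M": (9.0, 13.5),
                "tau": (0.7, 1.2),
                "sigma_max": (14.0, 28.0),
                "sigma_f": (14.0, 28.0),
                "sigma_r": (2.0, 14.0),
                "gamma1": (0.03, 0.3),
                "gamma2": (0.3, 0.8),
            },
            fixed={"f_tot": 14.5, "r_inc": 3.0, "r_dec": 3.0},
        )
    raise ValueError(f"no default search space for event {event}")


def nominal_athlete(event: int = 1500) -> AthleteParams:
    """Mid-box starting point used to seed the swarm and anchor the polish."""
    if event == 1500:
        return AthleteParams(
            e0=5500.0, f_M=11.0, tau=1.0, sigma_max=24.5, sigma_f=20.5,
            sigma_r=8.0, gamma1=0.25, gamma2=0.9, f_tot=14.0,
            r_inc=2.5, r_dec=2.5,
        )
    if event == 400:
        return AthleteParams(
            e0=3000.0, f_M=11.0, tau=0.9, sigma_max=22.0, sigma_f=22.0,
            sigma_r=6.0, gamma1=0.05, gamma2=0.35, f_tot=14.5,
            r_inc=3.0, r_dec=3.0,
        )
    raise ValueError(f"no nominal athlete for event {event}")


@dataclass(frozen=True)
class ObservedRace:
    """A fitting target: either a velocity trace or a split-time table."""

    event_distance: float
    track: TrackGeometry
    trace: VelocityTrace | None = None
    splits: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.trace is None) == (self.splits is None):
            raise ValueError("exactly one of trace/splits must be given")
        if self.splits is not None:
            d = np.array([x[0] for x in self.splits])
            t = np.array([x[1] for x in self.splits])
            if np.any(np.diff(d) <= 0) or np.any(np.diff(t) <= 0):
                raise ValueError("split distances and times must be strictly increasing")
            if abs(d[-1] - self.event_distance) > 1e-6:
                raise ValueError("last split distance must equal the event distance")

    @property
    def kind(self) -> str:
        return "trace" if self.trace is not None else "splits"


@dataclass(frozen=True)
class SearchSpace:
    """Bounds and fixed overrides defining the identification box.

    ``bounds`` maps free :class:`AthleteParams` field names to (lower,
    upper); ``fixed`` pins the remaining fields.  Fields in neither mapping
    fall back to the dataclass defaults.
    """

    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {f.name for f in dc_fields(AthleteParams)}
        for name in list(self.bounds) + list(self.fixed):
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"need lower < upper for {name!r}, got ({lo}, {hi})")
            if name in self.fixed:
                raise ValueError(f"{name!r} is both free and fixed")
        if not self.bounds:
            raise ValueError("search space has no free parameters")

    @property
    def free_names(self) -> list[str]:
        return sorted(self.bounds)

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        return lo, hi

    def make_params(self, x: Sequence[float]) -> AthleteParams:
        """Assemble an AthleteParams from a free-parameter vector.

        Raises ValueError if the combination violates parameter invariants
        (the objective converts that into the infeasibility penalty).
        """
        d = dict(self.fixed)
        d.update({n: float(v) for n, v in zip(self.free_names, x)})
        return AthleteParams(**d)

    @classmethod
    def around(
        cls, p: AthleteParams, spread: float, free: Sequence[str], **fixed_extra
    ) -> "SearchSpace":
        """Box of +-``spread`` (relative) around ``p`` for the ``free``
        fields, everything else fixed at ``p``'s values."""
        bounds = {
            n: (getattr(p, n) * (1 - spread), getattr(p, n) * (1 + spread))
            for n in free
        }
        fixed = {
            f.name: getattr(p, f.name) for f in dc_fields(AthleteParams)
            if f.name not in free
        }
        fixed.update(fixed_extra)
        return cls(bounds=bounds, fixed=fixed)


@dataclass
class IdentificationResult:
    """Outcome of a particle-swarm identification run."""

    best_params: AthleteParams
    objective: float
    history: list[float]
    seed: int
    evaluations: int
    sensitivity: dict[str, float] = dc_field(default_factory=dict)
    best_solution: RaceSolution | None = None


def _trace_to_distance(trace: VelocityTrace, event_distance: float):
    """Map a time-indexed trace to distance by cumulative trapezoidal
    integration of speed.

    If the integrated distance falls short of the event distance (chip
    timing offsets), the axis is uniformly rescaled so the last sample
    sits on the finish line; a trace that runs past the line keeps its
    natural scale and the overrun maps beyond D (model speed is clamped
    at the finish there)."""
    s_obs = cumulative_trapezoid(trace.speeds, trace.times, initial=0.0)
    if s_obs[-1] <= 0:
        raise ValueError("trace integrates to zero distance")
    if s_obs[-1] < event_distance:
        s_obs = s_obs * (event_distance / s_obs[-1])
    return s_obs


def _residuals(sol: RaceSolution, obs: ObservedRace) -> np.ndarray:
    """Signed model-minus-observation residual vector for one solution."""
    if obs.kind == "splits":
        interp = PchipInterpolator(sol.s_grid, sol.t)
        out = []
        for d, t_off in obs.splits:
            t_model = float(sol.T) if abs(d - obs.event_distance) < 1e-9 else float(interp(d))
            out.append(t_model - t_off)
        return np.array(out)
    s_obs = _trace_to_distance(obs.trace, obs.event_distance)
    # within a collocation cell w = v^2 is linear in s; interpolate in w
    v_model = np.sqrt(np.interp(s_obs, sol.s_grid, sol.v**2))
    return v_model - np.asarray(obs.trace.speeds)


def _score(residuals: np.ndarray, kind: str) -> float:
    # splits: sum of squared split-time errors (s^2); trace: MSE of speed
    return float(np.sum(residuals**2) if kind == "splits" else np.mean(residuals**2))


def fit_objective(
    p: AthleteParams,
    obs: ObservedRace,
    n_nodes: int = 300,
    warm_start: RaceSolution | None = None,
    solution_out: list | None = None,
    **solver_kwargs,
) -> float:
    """Discrepancy between the optimal race at ``p`` and the observation.

    Trace mode: mean squared difference between model and observed speed on
    the observed distance grid.  Splits mode: sum of squared differences of
    cumulative split times (s^2).  Parameter sets whose race cannot be
    solved score :data:`INFEASIBLE_PENALTY`.
    """
    try:
        sol = solve_min_time(p, obs.track, n_nodes=n_nodes, warm_start=warm_start,
                             **solver_kwargs)
    except (ValueError, FloatingPointError):
        return INFEASIBLE_PENALTY
    if sol.status == "failed" or not np.all(np.isfinite(sol.v)):
        return INFEASIBLE_PENALTY
    if solution_out is not None:
        solution_out.append(sol)
    return _score(_residuals(sol, obs), obs.kind)


def identify_parameters(
    obs: ObservedRace,
    space: SearchSpace,
    swarm_size: int = 24,
    iterations: int = 40,
    seed: int = 0,
    n_nodes: int = 300,
    polish_evals: int = 0,
    init: AthleteParams | None = None,
    search_tol: float = 1e-6,
    final_tol: float = 1e-7,
    search_maxiter: int = 150,
    final_maxiter: int = 400,
    final_time_weight: float = 1.0,
    compute_sensitivity: bool = True,
    **solver_kwargs,
) -> IdentificationResult:
    """Fit athlete parameters to an observed race by particle swarm search.

    Each particle is scored with :func:`fit_objective`; solves are
    warm-started from the best successfully solved race so far.  The swarm
    explores at solver accuracy ``search_tol``; ``polish_evals`` > 0 then
    refines the swarm's best point with a bounded Gauss-Newton
    (least-squares) pass on the residual vector at the tighter accuracy
    ``final_tol``, where solves are reproducible to ~1e-3 s so finite
    differences are reliable.  Deterministic for a fixed seed.
    """
    lo, hi = space.vector_bounds()
    width = hi - lo
    state = {"warm": None, "best_f": np.inf, "best_sol": None}
    n_eval_extra = 0

    def evaluate(x: np.ndarray, tol: float, maxiter: int):
        """Solve at x; returns (score, residuals or None, solution or None)."""
        try:
            p = space.make_params(x)
        except ValueError:
            return INFEASIBLE_PENALTY, None, None
        holder: list = []
        f = fit_objective(p, obs, n_nodes=n_nodes, warm_start=state["warm"],
                          solution_out=holder, tol=tol, maxiter=maxiter,
                          **solver_kwargs)
        if holder:
            sol = holder[0]
            if sol.status == "success" and f < state["best_f"]:
                state["best_f"] = f
                state["warm"] = sol
                state["best_sol"] = sol
            return f, _residuals(sol, obs), sol
        return f, None, None

    def objective(x: np.ndarray) -> float:
        return evaluate(x, search_tol, search_maxiter)[0]

    x_init = None
    if init is not None:
        x_init = np.array([getattr(init, n) for n in space.free_names])
    best_x, best_f, history, n_eval, (pbest, pbest_f) = particle_swarm(
        objective, lo, hi, swarm_size=swarm_size, iterations=iterations,
        seed=seed, init=x_init,
    )
    if best_f >= INFEASIBLE_PENALTY:
        raise RuntimeError("all particles infeasible: widen the search space")

    if polish_evals > 0:
        n_res = len(obs.splits) if obs.kind == "splits" else len(obs.trace.times)
        big = np.full(n_res, 1e3)
        wts = np.ones(n_res)
        if obs.kind == "splits" and final_time_weight != 1.0:
            wts[-1] = final_time_weight

        def make_resid(weights):
            def resid_scaled(z: np.ndarray) -> np.ndarray:
                nonlocal n_eval_extra
                n_eval_extra += 1
                _, r, _ = evaluate(lo + z * width, final_tol, final_maxiter)
                if r is None:
                    return big
                return (r if obs.kind == "splits" else r / np.sqrt(n_res)) * weights
            return resid_scaled

        def plain_score(r_weighted, weights):
            r = r_weighted / weights
            return _score(r, "splits") if obs.kind == "splits" else float(np.sum(r**2))

        dim = len(space.free_names)
        # polish starts (at most three, so each gets a workable step
        # budget): the swarm best, one distinct swarm elite, and the
        # nominal init as a seed-independent anchor
        starts = [(best_x - lo) / width]
        order = np.argsort(pbest_f)
        for j in order[1:]:
            if len(starts) >= 2 or pbest_f[j] >= INFEASIBLE_PENALTY:
                break
            z_j = (pbest[j] - lo) / width
            if all(np.max(np.abs(z_j - z0)) > 0.05 for z0 in starts):
                starts.append(z_j)
        if x_init is not None:
            z_i = (np.clip(x_init, lo, hi) - lo) / width
            if all(np.max(np.abs(z_i - z0)) > 0.05 for z0 in starts):
                starts.append(z_i)
        nfev_stage = max(6, polish_evals // ((len(starts) + 1) * (dim + 1)))
        # stage 1: plain residuals settle each candidate start into its
        # basin (the swarm best, plus the nominal init as a seed-independent
        # anchor); stage 2 refines the winner with the finishing-time
        # residual re-weighted (it is the most reliably timed observation)
        plain = np.ones(n_res)
        settled = []
        for z0 in starts:
            res = least_squares(
                make_resid(plain), z0, bounds=(0.0, 1.0),
                diff_step=0.02, max_nfev=nfev_stage,
                xtol=1e-12, ftol=1e-10, gtol=1e-14,
            )
            settled.append((plain_score(res.fun, plain), res.x))
        f1, z = min(settled, key=lambda c: c[0])
        res = least_squares(
            make_resid(wts), z, bounds=(0.0, 1.0),
            diff_step=0.02, max_nfev=nfev_stage,
            xtol=1e-12, ftol=1e-10, gtol=1e-14,
        )
        f_pol = plain_score(res.fun, wts)
        best_x = lo + res.x * width
        best_f = min(best_f, f1, f_pol)
        history.append(min(history[-1], best_f))

    best_params = space.make_params(best_x)
    # re-solve at the optimum so the reported solution matches best_params
    final_f, _, best_sol = evaluate(best_x, final_tol, 5 * final_maxiter)
    n_eval_extra += 1
    if best_sol is None:
        best_sol, final_f = state["best_sol"], best_f
    objective_value = float(min(best_f, final_f))
    if objective_value < history[-1]:
        history.append(objective_value)

    sens: dict[str, float] = {}
    for i, name in enumerate(space.free_names if compute_sensitivity else []):
        deltas = []
        for mult in (0.99, 1.01):
            x = best_x.copy()
            x[i] *= mult
            fp, _, _ = evaluate(np.clip(x, lo, hi), final_tol, final_maxiter)
            deltas.append(abs(fp - objective_value))
        sens[name] = float(np.nanmax(deltas))
        n_eval_extra += 2

    return IdentificationResult(
        best_params=best_params,
        objective=objective_value,
        history=history,
        seed=seed,
        evaluations=n_eval + n_eval_extra,
        sensitivity=sens,
        best_solution=best_sol,
    )
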