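"""Athlete physiology: parameters, aerobic power profile, and race dynamics.

All quantities are per unit body mass, so mass never enters the model.  The
runner's state along the race, parameterized by distance s, is

* ``t(s)``  elapsed time (s),
* ``v(s)``  velocity (m/s),
* ``f(s)``  propulsive force per unit mass (N/kg),
* ``e(s)``  residual anaerobic energy (J/kg), starting at the maximal
  accumulated oxygen deficit ``e0`` and constrained to stay non-negative.

The governing equations, written in distance, are::

    dt/ds = 1/v
    dv/ds = (f - v/tau) / v          Newton's law, linear friction v/tau
    df/ds = u / v,   u in [-r_dec, r_inc]    motor-control rate bounds
    de/ds = (sigma(e) - f*v) / v     energy balance

where ``sigma(e)`` is the aerobic (mechanical-equivalent) power supplied by
oxygen uptake.  Its three-phase profile — a rise at the start of the race,
a plateau, and an end-of-race decline — is indexed by residual anaerobic
energy rather than by distance: the phase switches happen at the fractions
``gamma2`` and ``gamma1`` of ``e0``.

On the bends, part of the total exertable force ``f_tot`` is consumed by
the centripetal demand ``v^2/R``, which caps the effective propulsive
force through ``f^2 + v^4/R^2 <= f_tot^2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AthleteParams",
    "RunnerState",
    "vo2_to_power",
    "power_to_vo2",
    "aerobic_power",
    "effective_force_bound",
    "dynamics",
    "JOULES_PER_ML_O2",
]

#: energy yield of oxygen: ~21.1 kJ per liter, i.e. 21.1 J per ml
JOULES_PER_ML_O2 = 21.1


def vo2_to_power(vo2: float) -> float:
    """Convert an oxygen uptake rate (ml O2 / kg / min) to aerobic power (W/kg).

    One liter of oxygen yields about 21.1 kJ through aerobic metabolism, so
    a VO2 of X ml/kg/min corresponds to X * 21.1 / 60 W/kg.
    """
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("VO2 must be non-negative")
    out = vo2 * JOULES_PER_ML_O2 / 60.0
    return float(out) if out.ndim == 0 else out


def power_to_vo2(power: float) -> float:
    """Inverse of :func:`vo2_to_power`: aerobic power (W/kg) to VO2 (ml/kg/min)."""
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("aerobic power must be non-negative")
    out = power * 60.0 / JOULES_PER_ML_O2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AthleteParams:
    """Identifiable physiological parameter set of one athlete.

    Attributes
    ----------
    e0:
        Total anaerobic energy store (maximal accumulated oxygen deficit),
        J/kg.
    f_M:
        Maximal propulsive force per unit mass, N/kg.
    f_tot:
        Total exertable force per unit mass, N/kg; on bends it is shared
        between propulsion and the centripetal effort, so ``f_M <= f_tot``.
    tau:
        Global friction coefficient (s); aggregates joint/track friction and
        air resistance and is linked to running economy.  The equilibrium
        (cruise) speed at propulsive power P is ``sqrt(P * tau)``.
    r_inc, r_dec:
        Maximal rates of increase/decrease of propulsive force, N/kg/s
        (motor control: effort cannot change instantaneously).
    sigma_max, sigma_f, sigma_r:
        Peak, end-of-race, and starting aerobic power levels (W/kg) of the
        three-phase profile.
    gamma1, gamma2:
        Residual-energy fractions (of e0) at which the profile changes
        phase: decline below ``gamma1*e0``, plateau up to ``gamma2*e0``,
        rise above.  ``0 < gamma1 < gamma2 < 1``.
    """

    e0: float
    f_M: float
    f_tot: float
    tau: float
    r_inc: float = 2.0
    r_dec: float = 2.0
    sigma_max: float = 25.0
    sigma_f: float = 22.0
    sigma_r: float = 7.5
    gamma1: float = 0.15
    gamma2: float = 0.9

    def __post_init__(self) -> None:
        positive = (
            "e0", "f_M", "f_tot", "tau", "r_inc", "r_dec",
            "sigma_max", "sigma_f", "sigma_r",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.gamma1 < self.gamma2 < 1:
            raise ValueError(
                f"need 0 < gamma1 < gamma2 < 1, got ({self.gamma1}, {self.gamma2})"
            )
        if self.sigma_f > self.sigma_max or self.sigma_r > self.sigma_max:
            raise ValueError("sigma_f and sigma_r must not exceed sigma_max")
        if self.f_M > self.f_tot:
            raise ValueError("f_M must not exceed f_tot")

    def replace(self, **changes) -> "AthleteParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AthleteParams":
        """Build from a flat mapping.  Aerobic levels may be given as VO2
        values in ml/kg/min under keys ``vo2_max``/``vo2_f``/``vo2_r``;
        they are converted to W/kg on load."""
        d = dict(d)
        for vo2_key, sigma_key in (
            ("vo2_max", "sigma_max"), ("vo2_f", "sigma_f"), ("vo2_r", "sigma_r"),
        ):
            if vo2_key in d:
                d[sigma_key] = vo2_to_power(d.pop(vo2_key))
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "AthleteParams":
        """Load from a JSON or YAML file (flat mapping, SI units)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class RunnerState:
    """Instantaneous state of the runner along the race."""

    t: float
    v: float
    f: float
    e: float


def aerobic_power(e, p: AthleteParams, smoothing: float = 0.0):
    """Aerobic power sigma(e) (W/kg) as a function of residual anaerobic energy.

    The profile is continuous and piecewise linear in e, traversed from
    ``e = e0`` (race start) downward:

    * rise phase, ``e >= gamma2*e0``: from ``sigma_r`` at the start up to
      ``sigma_max``;
    * plateau, ``gamma1*e0 <= e < gamma2*e0``: ``sigma_max``;
    * end-of-race decline, ``e < gamma1*e0``: down to ``sigma_f`` at e = 0.

    ``smoothing`` (dimensionless, fraction of the phase width) replaces the
    kinks by C^1 softplus corners; the optimizer uses a small positive value,
    reported values use the exact profile (0).  Accepts scalars or arrays.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < -1e-9) or np.any(e_arr > p.e0 * (1 + 1e-12) + 1e-9):
        raise ValueError(f"e outside [0, e0={p.e0}]")
    sig, _ = _aerobic_power_and_grad(e_arr, p, smoothing)
    return float(sig) if sig.ndim == 0 else sig


def _softplus(x, eps):
    """C^1 smoothed max(0, x): quadratic blend on |x| < eps, exact outside."""
    if eps == 0.0:
        return np.maximum(x, 0.0), (x > 0).astype(float)
    x = np.asarray(x, dtype=float)
    val = np.where(x <= -eps, 0.0,
                   np.where(x >= eps, x, (x + eps) ** 2 / (4.0 * eps)))
    grad = np.where(x <= -eps, 0.0,
                    np.where(x >= eps, 1.0, (x + eps) / (2.0 * eps)))
    return val, grad


def _aerobic_power_and_grad(e, p: AthleteParams, smoothing: float = 0.0):
    """sigma(e) and d sigma/d e, vectorized; used by the collocation solver."""
    e = np.asarray(e, dtype=float)
    rise_width = (1.0 - p.gamma2) * p.e0
    fall_width = p.gamma1 * p.e0
    # rise phase deficit: how far e still is above the plateau threshold
    x_rise = (e - p.gamma2 * p.e0) / rise_width
    x_fall = (fall_width - e) / fall_width
    pr, dpr = _softplus(x_rise, smoothing)
    pf, dpf = _softplus(x_fall, smoothing)
    sigma = p.sigma_max - (p.sigma_max - p.sigma_r) * pr - (p.sigma_max - p.sigma_f) * pf
    grad = (
        -(p.sigma_max - p.sigma_r) * dpr / rise_width
        + (p.sigma_max - p.sigma_f) * dpf / fall_width
    )
    return sigma, grad


def effective_force_bound(v, kappa, f_tot: float):
    """Largest propulsive force compatible with the bend constraint.

    On a bend of curvature kappa the centripetal demand ``v^2 * kappa``
    consumes part of the total exertable force:
    ``f^2 + v^4 * kappa^2 <= f_tot^2``, so the effective cap is
    ``sqrt(f_tot^2 - v^4 kappa^2)``.  Raises if the speed itself is
    infeasible for the bend.
    """
    v = np.asarray(v, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(v < 0) or np.any(kappa < 0):
        raise ValueError("v and kappa must be non-negative")
    slack = f_tot**2 - v**4 * kappa**2
    if np.any(slack < -1e-12):
        raise ValueError("speed infeasible for the bend: v^4 kappa^2 > f_tot^2")
    out = np.sqrt(np.maximum(slack, 0.0))
    return float(out) if out.ndim == 0 else out


def dynamics(state: RunnerState, force_rate: float, p: AthleteParams, kappa: float):
    """Right-hand side of the race ODEs in distance: (dt/ds, dv/ds, df/ds, de/ds).

    ``force_rate`` is the motor-control input df/dt in N/kg/s, bounded by
    ``[-r_dec, r_inc]``.  The curvature ``kappa`` does not enter the
    equations of motion directly; it acts through the bend force bound
    enforced by the solver.
    """
    if state.v <= 0:
        raise ValueError("dynamics are singular at v <= 0")
    if not -p.r_dec - 1e-12 <= force_rate <= p.r_inc + 1e-12:
        raise ValueError(f"force_rate {force_rate} outside [-r_dec, r_inc]")
    sigma = aerobic_power(state.e, p)
    dt_ds = 1.0 / state.v
    dv_ds = (state.f - state.v / p.tau) / state.v
    df_ds = force_rate / state.v
    de_ds = (sigma - state.f * state.v) / state.v
    return dt_ds, dv_ds, df_ds, de_ds
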