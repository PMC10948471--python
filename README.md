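# paceopt

Minimum-time optimal-control modelling of 400 m and 1500 m track running.

`paceopt` is for exercise physiologists, performance analysts and applied
mathematicians who want to turn race timing data — official 100 m split
tables or 10 Hz instantaneous-velocity feeds from in-stadium athlete
tracking — into a mechanistic account of a performance: instantaneous
propulsive force, aerobic and anaerobic energy use, the cost of the bends,
and the effect of changing any single physiological parameter.

## The model

The runner's state along the race distance *s* is velocity *v*, propulsive
force per unit mass *f*, and residual anaerobic energy *e* (the maximal
accumulated oxygen deficit, spent from an initial store *e⁰*). The race is
the minimum-time trajectory of

    dv/dt = f − v/τ                    (Newton's law, linear friction)
    df/dt = u,  u ∈ [−r_dec, r_inc]    (motor control: effort cannot jump)
    de/dt = σ(e) − f·v                 (energy balance)

subject to 0 ≤ f ≤ f_M, e ≥ 0, and on bends of radius *R* the centripetal
demand shares the total force budget:

    f² + v⁴/R² ≤ f_tot².

σ(e) is the aerobic power supplied by oxygen uptake (VO₂ × 21.1 J/ml),
with a three-phase profile indexed by residual anaerobic energy: a rise
from σ_r at the gun, a plateau at σ_max once a fraction (1−γ₂) of the
store is spent, and a decline toward σ_f below γ₁·e⁰.

The optimal control problem is transcribed by direct collocation in the
squared velocity (which removes the 1/v start singularity) and solved as a
nonlinear program; athlete parameters are identified from observed races
by particle swarm search over a physiological box with a Gauss–Newton
polish, where each candidate is scored by solving its full optimal race.

## Worked example

```python
from paceopt import build_track, preset_athletes, solve_min_time, race_summary

track = build_track(1500)                      # lane-1 path, curved start
athlete = preset_athletes()["miler_m"]         # world-class male miler preset
sol = solve_min_time(athlete, track, n_nodes=120)
print(f"T = {sol.T:.2f} s")
print(race_summary(sol, athlete, series=False))
```

prints (see `examples/simulate_1500m.py` for the full script):

```
T = 202.98 s
{'T': 202.98, 'anaerobic_ratio': 0.446, 'aerobic_ratio': 0.554,
 'anaerobic_energy': 4400.0, 'aerobic_energy': 5455.0,
 'peak_speed': 10.08, 'peak_speed_distance': 18.0}
```

— a 3:22.98 race with the hallmark shape of championship middle-distance
running: a fast start peaking at ~10 m/s inside the first 20 m, a high
cruise, and an anaerobic share of ~45% of the total energy turnover, with
the store exhausted exactly at the line.

The other example scripts cover the rest of the surface: lane effects on
the 400 m (`lane_effects_400m.py`), identification from an official split
table (`fit_official_race.py`), parameter recovery from synthetic 10 Hz
traces (`parameter_recovery.py`), and what-if scenario studies
(`what_if_scenarios.py`). A thin CLI wraps the same pipeline:
`paceopt simulate|fit|perturb|lanes|synth|summary --help`.

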