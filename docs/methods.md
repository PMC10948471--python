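# Methods

## Model

A race is modelled per unit body mass; mass never enters. With distance
*s* as the independent variable, the runner's state is velocity *v(s)*,
propulsive force *f(s)*, and residual anaerobic energy *e(s)*:

    dt/ds = 1/v
    dv/ds = (f − v/τ)/v
    df/ds = u/v,        u ∈ [−r_dec, r_inc]
    de/ds = (σ(e) − f v)/v

* **τ (s)** — global friction coefficient: a single linear damping term
  aggregating joint, track and air resistance; linked to running economy.
  At constant propulsive power *P* the equilibrium speed is √(P·τ).
* **f_M, f_tot (N/kg)** — maximal propulsive force, and the total force
  budget that on bends is shared with the centripetal demand through
  f² + v⁴κ² ≤ f_tot², κ = 1/R. The bend constraint is the only way
  curvature enters the dynamics.
* **e⁰ (J/kg)** — anaerobic store (maximal accumulated oxygen deficit).
  The optimum always exhausts it exactly at the line.
* **σ(e) (W/kg)** — aerobic power; VO₂ in ml/kg/min converts at
  21.1 J per ml of O₂ (so 60 ml/kg/min ↔ 21.1 W/kg). The profile is
  continuous and piecewise linear in *e*, traversed downward from e⁰:
  a rise from σ_r to σ_max while *e* falls to γ₂·e⁰, a plateau at σ_max,
  and a decline to σ_f below γ₁·e⁰. Indexing the phases by residual
  energy rather than distance makes the same parameterization serve both
  events: sprint-like profiles (VO₂ still rising late in the race) simply
  have small γ₂. The exact functional form of the rise and decline is a
  modelling choice here (linear in *e*); only the three-phase structure
  is essential.
* **r_inc, r_dec (N/kg/s)** — motor-control bounds on how fast effort can
  build or release. Force at the gun, f(0), is free within its bounds:
  the rate limits act along the race, not at the start.

Defaults in the preset athletes place a world-class male miler at
e⁰ ≈ 4400 J/kg, τ ≈ 1.13 s, σ_max ≈ 27.4 W/kg (VO₂ 78 ml/kg/min) with a
10% end-race decline — values that give a ~3:23 optimal 1500 m with an
anaerobic share of ~45% — and 400 m presets whose anaerobic share is
ante ~75%. Presets are synthetic fixtures for tests and examples, not
reconstructions of real athletes.

## Track geometry

A standard outdoor track: 84 m straights, 116 m bends along the lane-1
measurement line (0.30 m outside the kerb, radius 36.5 m). Lane *n* adds
w·(n−1) to the bend radius (lane width w = 1.22 m, configurable); its full
bend is 116 + π·w·(n−1) m of arc, and the 400 m stagger 2π·w·(n−1) is
removed from the first bend so every lane covers exactly 400 m. The
printed bend length (116 m) and curvature (1/36.5) are both kept verbatim
even though π·36.5 ≈ 114.7 m — the small discrepancy is the measurement
line offset, and keeping both published values exact was preferred to
deriving one from the other. The 1500 m starts from the curved line at
the head of the back straight, modelled as a 16 m bend stub followed by
straight/bend alternation through 3¾ laps; the stub length is a
convention fixed by requiring an exact 1500 m ending at the common
finish.

## Numerics of the minimum-time solve

Direct collocation on a distance grid, with the squared velocity
w = v² as the speed variable. In *w* the start is regular:
dw/ds = 2f − 2√w/τ is bounded even at the near-standing start
(v(0) = 1 m/s by default — the distance parameterization is singular at
v = 0, so the first metre is started rolling). Two discretization choices
matter and were chosen after the obvious ones failed:

* **Cell time.** With *w* piecewise linear in *s* (the collocation
  ansatz), ∫ds/√w over a cell is exactly 2Δs/(v_i + v_{i+1}); a
  trapezoid of 1/v instead overprices the steep start cells by several
  tenths of a second and the bias does not shrink with the bulk grid.
* **Cell energy balance.** The aerobic term is priced as σ̄·Δt with the
  same cell time Δt, never as a trapezoid of σ/v: endpoint sampling of
  σ/v lets a coarse grid manufacture aerobic energy at slow nodes, and
  the optimizer will find and exploit that leak.

The grid puts ~9 graded cells over the first 30 m and relaxes
geometrically (factor ≤ 1.3 per cell) into a uniform bulk; n_nodes counts
cells (default 300; identification uses 60, see below). Variables are
scaled to O(1) (w/100, f/10, e/(e⁰/15)), the NLP is solved with SLSQP
with hand-coded dense Jacobians, and a tiny quadratic penalty on force
increments (weight 1e-6, switchable) selects a smooth representative
among near-optimal force profiles. The σ(e) corners are C¹-smoothed over
a configurable fraction of each phase width (default 0.1) for the
optimizer only; reported σ series use the exact piecewise profile. The
smoothing shifts T by under 0.03 s while cutting SLSQP iteration counts
about threefold.

A solution is `success` when SLSQP converges and the scaled constraint
violation is ≤ 10× the tolerance (default 1e-6); near-feasible
iterates (violation ≤ 1e-4) are labelled `tolerance_not_met` and still
usable — identification treats them as valid but never warm-starts from
them. Grid convergence on the 1500 m reference problem is ~0.03 s
between 60 and 240 cells.

**Degenerate inputs.** Two regimes are known to strain the NLP: a
constant σ(e) (no rise/decline) combined with a small store on a long
flat course makes the energy allocation a flat valley and can leave an
extended e = 0 arc whose active set is degenerate; and extreme parameter
corners during swarm search may fail outright (they score a fixed
penalty, 1e6, in the identification objective). The test suite's
closed-form cruise check (v* = √(σ_max·τ) within 1%) therefore uses a
plateau-dominated three-phase profile rather than a literally constant σ.

## Identification

The fitting target is either a split table (objective: sum of squared
cumulative-time errors) or a 10 Hz velocity trace (objective: mean squared
speed error after mapping the trace to distance by cumulative trapezoidal
integration and uniform rescaling to the event distance). The model
prediction is always the minimum-time optimal race at the candidate
parameters — identification asks "which physiology makes this performance
optimal", not "which force profile reproduces it".

The search is a global-best particle swarm (inertia 0.729,
cognitive/social 1.49, box-clipped, velocity-clamped; our own
implementation on a seeded numpy generator) over a bounded physiological
box, warm-starting each solve from the best successfully solved race so
far. The swarm explores at solver tolerance 1e-6 where solves are cheap
but only reproducible to a few hundredths of a second in the splits;
the polish then switches to 1e-7, where solves are reproducible to
~2 ms, and runs bounded Gauss–Newton (`scipy.optimize.least_squares`,
trust-region reflective) on the residual vector with relative finite
differences of 2% of the box width — far above solve noise. The polish
settles two starting points (the swarm best and a fixed nominal athlete,
which makes the outcome robust to unlucky seeds) and then optionally
re-weights the finishing-time residual (weight 8 in the official-race
fits): the final time is the most reliably measured entry of a split
table, and plain least squares will otherwise trade it against the
mid-race residuals. Reported objectives are always unweighted. Every run
is deterministic for a fixed seed; the result carries the best-objective
history (non-increasing by construction) and a per-parameter ±1%
sensitivity so ill-determined directions are visible.

**Identifiability.** A 100 m split table pins some parameters far better
than others. On the package's own forward model, raising e⁰ by 10% with a
compensating ~5% change in τ moves the fifteen cumulative splits by only a
few milliseconds RMS — below the reproducibility of fully converged
solves — so the anaerobic store is identifiable from 100 m splits only to
roughly ±10%, while σ_max resolves to ~1–2% and τ to ~5%. A 10 Hz trace,
with two thousand observations covering the start and sprint transients,
constrains e⁰ several times more tightly. The per-parameter sensitivity
reported with every identification makes such degenerate directions
visible rather than hidden; recovery claims should always be read against
it.

For the official-race fits, e⁰, f_M, τ, σ_max, σ_f, σ_r, γ₁ and γ₂ are
free; f_tot and the rate bounds are fixed (neither is identifiable from
100 m splits — the bend-force margin and the ramp shape move the splits
by far less than the official timing resolution). Identification runs on
a 60-cell grid: the fit compares model and data on the same grid, so the
~0.1 s coarse-grid bias is absorbed into the identified parameters
rather than the residuals, and a 60-cell solve is ~20× cheaper than a
300-cell one — the swarm needs hundreds of solves per race.

## Synthetic data

`generate_trace` emulates the in-stadium tracking feed: the optimal race
is solved, v(s) is converted to v(t), sampled at 10 Hz, and i.i.d.
zero-mean Gaussian noise (default sd 0.08 m/s) is added and clipped at
zero. Real feeds differ in ways the generator deliberately ignores:
their noise is filtered and autocorrelated, samples can drop out, and the
athlete's path wanders off the measurement line. Passing the recovery
experiments therefore shows the pipeline is consistent under the stated
noise model, not that real-feed noise is harmless. Split tables derived
from solutions are exact to interpolation.

## What the acceptance script measures

`scripts/acceptance.py` fits the three packaged official 1500 m split
tables (swarm 12 × 8 iterations, 60-cell grid, two-stage polish — the
problem sizes chosen for a desk-scale run) and reports the worst-race
final-time error and the pooled share of 100 m splits within 0.1 s. The
final-time error lands in the few-millisecond range. The pooled split
share lands near half: the residual is dominated by in-race tactical
pacing — surges and lulls in championship racing — which no minimum-time
solution of this model family can reproduce, whatever the parameters.
That is a structural property of fitting optimal races to tactical ones,
not a solver artifact: the same residual wave (a few tenths of a second,
alternating sign over 300–700 m) appears at every local optimum found.

## Known limitations

* Optimality is local (SLSQP from a documented initial guess); no global
  certificate. On a flat-track toy problem the solver agrees with an
  independent dynamic-programming oracle to <1%.
* f_tot is constant: the transient effort of leaning into and out of
  bends is not rate-limited.
* No drafting, wind, altitude, or multi-athlete interaction; oxygen-debt
  repayment after the line is out of scope.
* The aerobic profile is tied to residual energy; athletes whose VO₂
  drift is time- rather than energy-driven are outside the model class.
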