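"""Shared fixtures: tracks, preset athletes, and cached reference solves.

Expensive optimal-control solves, the dynamic-programming oracle, and the
parameter-recovery experiments are session-scoped so that unit and
acceptance tests can share them; coarse grids (45-60 intervals) keep
individual solves below a few seconds while remaining well inside the
solver's convergent regime.
"""

import numpy as np
import pytest

import paceopt as po
from paceopt.identify import ObservedRace, SearchSpace, identify_parameters
from paceopt.ocp import splits as compute_splits


@pytest.fixture(scope="session")
def track400():
    return po.build_track(400, lane=1)


@pytest.fixture(scope="session")
def track400_lane4():
    return po.build_track(400, lane=4)


@pytest.fixture(scope="session")
def track1500():
    return po.build_track(1500)


@pytest.fixture(scope="session")
def presets():
    return po.preset_athletes()


@pytest.fixture(scope="session")
def miler(presets):
    return presets["miler_m"]


@pytest.fixture(scope="session")
def sprinter(presets):
    return presets["sprinter_m"]


@pytest.fixture(scope="session")
def miler_race(miler, track1500):
    """Reference 1500 m solve for the male miler preset."""
    sol = po.solve_min_time(miler, track1500, n_nodes=60)
    assert sol.success
    return sol


@pytest.fixture(scope="session")
def sprint_race(sprinter, track400):
    """Reference 400 m solve for the male sprinter preset."""
    sol = po.solve_min_time(sprinter, track400, n_nodes=60)
    assert sol.success
    return sol


def straight_track(length: float) -> po.TrackGeometry:
    """A bend-free track of the given length (test helper)."""
    return po.TrackGeometry(
        event_distance=length,
        lane=1,
        segments=(po.TrackSegment(length, 0.0),),
        bend_radius=36.5,
    )


@pytest.fixture(scope="session")
def keller_athlete():
    """A small anaerobic store and a plateau-dominated aerobic profile:
    mid-race the runner sits in the friction-limited cruise regime where
    v* = sqrt(sigma_max * tau)."""
    return po.AthleteParams(
        e0=60.0, f_M=8.0, f_tot=9.0, tau=1.2,
        r_inc=50.0, r_dec=50.0,
        sigma_max=25.0, sigma_f=20.0, sigma_r=20.0,
        gamma1=0.1, gamma2=0.9,
    )


@pytest.fixture(scope="session")
def toy_oracle_pair():
    """Collocation vs dynamic-programming oracle on the 100 m toy problem.

    Flat track, constant aerobic power, binding anaerobic store,
    effectively unconstrained motor control.
    """
    from dp_oracle import dp_min_time

    tau, f_max, sigma, e0 = 1.0, 9.0, 5.0, 600.0
    p = po.AthleteParams(
        e0=e0, f_M=f_max, f_tot=f_max + 0.5, tau=tau,
        r_inc=500.0, r_dec=500.0,
        sigma_max=sigma, sigma_f=sigma, sigma_r=sigma,
        gamma1=0.3, gamma2=0.6,
    )
    sol = po.solve_min_time(p, straight_track(100.0), n_nodes=60)
    assert sol.success
    T_dp = dp_min_time(100.0, tau, f_max, sigma, e0, ds=0.5, n_w=160,
                       n_e=110, n_f=61)
    return sol.T, T_dp


@pytest.fixture(scope="session")
def miler_splits_obs(miler, track1500, miler_race):
    """Noiseless split table generated by the forward solver itself."""
    table = tuple(compute_splits(miler_race, 100.0))
    return ObservedRace(event_distance=1500.0, track=track1500, splits=table)


@pytest.fixture(scope="session")
def splits_recovery(miler, miler_splits_obs):
    """Recover (e0, tau, sigma_max) from the model's own noiseless splits,
    bounds +-50% around the truth."""
    space = SearchSpace.around(miler, 0.5, ["e0", "tau", "sigma_max"])
    return identify_parameters(
        miler_splits_obs, space, swarm_size=16, iterations=14, seed=3,
        n_nodes=60, polish_evals=300,
    )


@pytest.fixture(scope="session")
def trace_recovery(miler, track1500):
    """Recover (e0, tau) from a noisy 10 Hz trace (sd 0.08 m/s)."""
    trace = po.generate_trace(miler, track1500, noise_sd=0.08, seed=7, n_nodes=60)
    obs = ObservedRace(event_distance=1500.0, track=track1500, trace=trace)
    space = SearchSpace.around(miler, 0.5, ["e0", "tau"])
    return identify_parameters(
        obs, space, swarm_size=8, iterations=6, seed=5,
        n_nodes=60, polish_evals=80,
    )
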