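"""Minimum-time solver: analytic limits, oracles, invariants, summaries."""

import numpy as np
import pytest

import paceopt as po
from paceopt.ocp import RaceSolution, race_summary, splits

from conftest import straight_track


class TestKellerCruise:
    def test_cruise_speed_matches_closed_form(self, keller_athlete):
        # a small anaerobic store spread over a long flat race: mid-race
        # speed settles at the friction-limited plateau equilibrium
        # v* = sqrt(sigma_max * tau)
        p = keller_athlete
        track = straight_track(1200.0)
        sol = po.solve_min_time(p, track, n_nodes=60)
        assert sol.success
        v_star = np.sqrt(p.sigma_max * p.tau)
        mid = (sol.s_grid > 480.0) & (sol.s_grid < 720.0)
        assert np.all(np.abs(sol.v[mid] - v_star) / v_star < 0.01)


class TestBruteForceOracle:
    def test_toy_instance_within_one_percent(self, toy_oracle_pair):
        # 100 m flat toy problem, energy-limited, effectively no motor
        # control limits: compare against an independent dynamic-programming
        # oracle on a dense (v^2, e) grid
        T_colloc, T_dp = toy_oracle_pair
        assert abs(T_colloc - T_dp) / T_dp < 0.01


class TestMonotonicity:
    def test_more_anaerobic_energy_is_faster(self, miler, track1500, miler_race):
        bigger = miler.replace(e0=1.05 * miler.e0)
        sol = po.solve_min_time(bigger, track1500, n_nodes=60,
                                warm_start=miler_race)
        assert sol.success
        assert sol.T < miler_race.T


class TestSolutionInvariants:
    def test_time_monotone_and_positive_speed(self, miler_race):
        assert np.all(np.diff(miler_race.t) > 0)
        assert np.all(miler_race.v > 0)

    def test_energy_within_bounds(self, miler_race, miler):
        assert np.all(miler_race.e >= -1e-9)
        assert np.all(miler_race.e <= miler.e0 + 1e-9)

    def test_bend_constraint_at_all_nodes(self, sprint_race, sprinter, track400):
        kappa = np.array([track400.curvature_at(float(s)) for s in sprint_race.s_grid])
        lhs = sprint_race.f**2 + sprint_race.v**4 * kappa**2
        assert np.all(lhs <= sprinter.f_tot**2 * (1 + 1e-6))

    def test_energy_bookkeeping(self, miler_race, miler):
        # e0 - e(T) + int sigma dt = int f v dt, evaluated by an
        # independent trapezoid quadrature on the time grid
        anaerobic = miler.e0 - miler_race.e[-1]
        aerobic = np.trapezoid(miler_race.sigma, miler_race.t)
        work = np.trapezoid(miler_race.f * miler_race.v, miler_race.t)
        assert anaerobic + aerobic == pytest.approx(work, rel=0.02)

    def test_grid_refinement_stability(self, miler, track1500, miler_race):
        fine = po.solve_min_time(miler, track1500, n_nodes=120,
                                 warm_start=miler_race)
        assert fine.success
        assert abs(fine.T - miler_race.T) < 0.05


class TestSprintShape:
    def test_peak_speed_early_then_slowdown(self, sprint_race):
        # all-out 400 m: peak within the first 100 m, then a continual
        # slowdown: each 100 m segment is slower than the last, and any
        # bend-exit re-acceleration stays small
        i_peak = int(np.argmax(sprint_race.v))
        assert sprint_race.s_grid[i_peak] < 100.0
        seg_means = [
            sprint_race.v[(sprint_race.s_grid >= a) & (sprint_race.s_grid < a + 100)].mean()
            for a in (100.0, 200.0, 300.0)
        ]
        assert seg_means[0] > seg_means[1] > seg_means[2]
        assert np.all(np.diff(sprint_race.v[i_peak:]) < 0.5)

    def test_bend_constraint_active_on_first_bend(self, sprint_race, sprinter, track400):
        kappa = np.array([track400.curvature_at(float(s)) for s in sprint_race.s_grid])
        first_bend = (sprint_race.s_grid < 116.0) & (kappa > 0) & (sprint_race.s_grid > 30.0)
        slack = sprinter.f_tot**2 - (
            sprint_race.f[first_bend] ** 2
            + sprint_race.v[first_bend] ** 4 * kappa[first_bend] ** 2
        )
        assert slack.min() < 0.05 * sprinter.f_tot**2


class TestSplits:
    def test_uniform_motion(self):
        s = np.linspace(0.0, 1500.0, 151)
        sol = RaceSolution(
            s_grid=s, t=s / 5.0, v=np.full_like(s, 5.0),
            f=np.zeros_like(s), e=np.zeros_like(s), sigma=np.zeros_like(s),
            T=300.0, status="success", max_constraint_violation=0.0,
        )
        out = splits(sol, 100.0)
        gaps = np.diff([0.0] + [t for _, t in out])
        assert gaps == pytest.approx(np.full(15, 20.0))

    def test_last_split_equals_final_time(self, miler_race):
        out = splits(miler_race, 100.0)
        assert out[-1] == (1500.0, miler_race.T)

    def test_empty_solution_rejected(self):
        sol = RaceSolution(
            s_grid=np.array([]), t=np.array([]), v=np.array([]),
            f=np.array([]), e=np.array([]), sigma=np.array([]),
            T=0.0, status="failed", max_constraint_violation=np.inf,
        )
        with pytest.raises(ValueError):
            splits(sol)


class TestRaceSummary:
    def _constant_solution(self, sigma_level, e_start, e_end):
        s = np.linspace(0.0, 1000.0, 101)
        t = s / 5.0
        e = np.linspace(e_start, e_end, 101)
        return RaceSolution(
            s_grid=s, t=t, v=np.full_like(s, 5.0), f=np.full_like(s, 4.0),
            e=e, sigma=np.full_like(s, sigma_level), T=float(t[-1]),
            status="success", max_constraint_violation=0.0,
        )

    def test_pure_anaerobic(self):
        p = po.AthleteParams(e0=2000.0, f_M=9.0, f_tot=10.0, tau=1.0)
        sol = self._constant_solution(0.0, 2000.0, 500.0)
        assert race_summary(sol, p)["anaerobic_ratio"] == pytest.approx(1.0)

    def test_pure_aerobic(self):
        p = po.AthleteParams(e0=2000.0, f_M=9.0, f_tot=10.0, tau=1.0)
        sol = self._constant_solution(20.0, 2000.0, 2000.0)
        assert race_summary(sol, p)["anaerobic_ratio"] == pytest.approx(0.0)

    def test_against_independent_quadrature(self, miler_race, miler):
        out = race_summary(miler_race, miler)
        aerobic = np.trapezoid(miler_race.sigma, miler_race.t)
        anaerobic = miler.e0 - miler_race.e[-1]
        assert out["anaerobic_ratio"] == pytest.approx(
            anaerobic / (anaerobic + aerobic), rel=1e-9
        )
        assert out["aerobic_ratio"] + out["anaerobic_ratio"] == pytest.approx(1.0)
        inst = out["instantaneous_anaerobic_ratio_series"]
        assert np.all((0.0 <= inst) & (inst <= 1.0))

    def test_csv_export_round_trip(self, tmp_path, miler_race, miler):
        import json
        import pandas as pd

        path = tmp_path / "race.csv"
        miler_race.to_csv(path, miler)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "s_m", "t_s", "v_mps", "f_Npkg", "e_Jpkg", "vo2_mlkgmin"
        ]
        assert df["t_s"].iloc[-1] == pytest.approx(miler_race.T)
        meta = json.loads(path.with_suffix(".csv.json").read_text())
        assert meta["T"] == pytest.approx(miler_race.T)
        assert 0.0 < meta["anaerobic_ratio"] < 1.0
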