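"""Aerobic profile, VO2 conversion, bend force bound, and dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paceopt as po
from paceopt.energetics import RunnerState


@pytest.fixture(scope="module")
def params():
    return po.AthleteParams(
        e0=1500.0, f_M=9.0, f_tot=10.0, tau=1.0,
        sigma_max=25.0, sigma_f=20.0, sigma_r=7.5, gamma1=0.2, gamma2=0.8,
    )


class TestVO2Conversion:
    @pytest.mark.parametrize(
        "vo2,power",
        [(0.0, 0.0), (60.0, 21.1), (78.0, 27.43)],
    )
    def test_values(self, vo2, power):
        assert po.vo2_to_power(vo2) == pytest.approx(power, abs=5e-3)

    @given(st.floats(0.0, 120.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, vo2):
        assert po.power_to_vo2(po.vo2_to_power(vo2)) == pytest.approx(
            vo2, abs=1e-12, rel=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            po.vo2_to_power(-1.0)


class TestAerobicPower:
    def test_phase_boundaries(self, params):
        e0 = params.e0
        assert po.aerobic_power(e0, params) == pytest.approx(params.sigma_r)
        mid_plateau = 0.5 * (params.gamma1 + params.gamma2) * e0
        assert po.aerobic_power(mid_plateau, params) == pytest.approx(params.sigma_max)
        mid_decline = 0.5 * params.gamma1 * e0
        assert po.aerobic_power(mid_decline, params) == pytest.approx(
            0.5 * (params.sigma_f + params.sigma_max)
        )
        assert po.aerobic_power(0.0, params) == pytest.approx(params.sigma_f)

    def test_continuous_and_bounded(self, params):
        e = np.linspace(0.0, params.e0, 4001)
        sig = po.aerobic_power(e, params)
        lo = min(params.sigma_r, params.sigma_f)
        assert np.all(sig <= params.sigma_max + 1e-12)
        assert np.all(sig >= lo - 1e-12)
        # no jump anywhere on a dense grid
        assert np.max(np.abs(np.diff(sig))) < 0.05

    def test_out_of_range(self, params):
        with pytest.raises(ValueError):
            po.aerobic_power(-1.0, params)
        with pytest.raises(ValueError):
            po.aerobic_power(params.e0 + 1.0, params)


class TestForceBound:
    def test_straight_returns_f_tot(self):
        assert po.effective_force_bound(8.0, 0.0, 10.0) == 10.0

    def test_boundary_zero(self):
        # v^4 kappa^2 exactly f_tot^2
        v, f_tot = 8.0, 10.0
        kappa = f_tot / v**2
        assert po.effective_force_bound(v, kappa, f_tot) == pytest.approx(0.0, abs=1e-9)

    def test_bend_arithmetic(self):
        val = po.effective_force_bound(9.0, 1 / 36.5, 10.0)
        assert val == pytest.approx(np.sqrt(100.0 - 9.0**4 / 36.5**2))
        assert val == pytest.approx(9.751, abs=1e-3)

    def test_infeasible_speed(self):
        with pytest.raises(ValueError, match="infeasible"):
            po.effective_force_bound(12.0, 1 / 10.0, 5.0)

    @given(
        v=st.floats(0.0, 10.0),
        kappa=st.floats(0.0, 1 / 36.5),
        v2=st.floats(0.0, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_nonincreasing_in_speed_and_curvature(self, v, kappa, v2):
        f_tot = 12.0
        lo_v, hi_v = sorted([v, v2])
        assert po.effective_force_bound(hi_v, kappa, f_tot) <= po.effective_force_bound(
            lo_v, kappa, f_tot
        ) + 1e-12
        assert po.effective_force_bound(v, kappa, f_tot) <= po.effective_force_bound(
            v, 0.0, f_tot
        ) + 1e-12


class TestDynamics:
    def test_mechanical_equilibrium(self, params):
        state = RunnerState(t=10.0, v=6.0, f=6.0 / params.tau, e=0.5 * params.e0)
        _, dv_ds, _, _ = po.dynamics(state, 0.0, params, 0.0)
        assert dv_ds == pytest.approx(0.0, abs=1e-12)

    def test_energy_balance_equilibrium(self, params):
        e = 0.5 * params.e0  # plateau: sigma = sigma_max
        v = 5.0
        f = params.sigma_max / v
        state = RunnerState(t=0.0, v=v, f=f, e=e)
        _, _, _, de_ds = po.dynamics(state, 0.0, params, 0.0)
        assert de_ds == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_rhs(self, params):
        # v=8, tau=1, f=9, plateau sigma=25: dv/ds=(9-8)/8, de/ds=(25-72)/8
        state = RunnerState(t=0.0, v=8.0, f=9.0, e=0.5 * params.e0)
        dt_ds, dv_ds, df_ds, de_ds = po.dynamics(state, 0.5, params, 0.0)
        assert dt_ds == pytest.approx(1 / 8)
        assert dv_ds == pytest.approx(0.125)
        assert df_ds == pytest.approx(0.5 / 8)
        assert de_ds == pytest.approx(-5.875)

    def test_singular_at_rest(self, params):
        with pytest.raises(ValueError):
            po.dynamics(RunnerState(0.0, 0.0, 5.0, 100.0), 0.0, params, 0.0)

    def test_force_rate_bounds_enforced(self, params):
        state = RunnerState(0.0, 5.0, 5.0, 100.0)
        with pytest.raises(ValueError):
            po.dynamics(state, params.r_inc + 1.0, params, 0.0)


class TestParamsValidation:
    def test_gamma_ordering(self):
        with pytest.raises(ValueError):
            po.AthleteParams(e0=1000, f_M=9, f_tot=10, tau=1.0, gamma1=0.8, gamma2=0.3)

    def test_sigma_f_cap(self):
        with pytest.raises(ValueError):
            po.AthleteParams(
                e0=1000, f_M=9, f_tot=10, tau=1.0, sigma_max=20.0, sigma_f=25.0
            )

    def test_f_M_cap(self):
        with pytest.raises(ValueError):
            po.AthleteParams(e0=1000, f_M=11, f_tot=10, tau=1.0)

    def test_vo2_keys_converted(self):
        p = po.AthleteParams.from_dict(
            dict(e0=1000, f_M=9, f_tot=10, tau=1.0, vo2_max=78.0, vo2_f=70.0, vo2_r=20.0)
        )
        assert p.sigma_max == pytest.approx(po.vo2_to_power(78.0))
        assert p.sigma_f == pytest.approx(po.vo2_to_power(70.0))

    def test_json_round_trip(self, tmp_path, params):
        path = tmp_path / "p.json"
        params.to_json(path)
        assert po.AthleteParams.from_file(path) == params
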