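import json
import math
import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from radkin import (
    CaseConfig,
    GrowthParams,
    RadiobiologyConstants,
    TreatmentSpec,
    integrate_numeric,
    phase2_closed_form,
    simulate,
    simulate_standard_model,
)
from radkin.growth import LN2, gompertz_volume
from radkin.radiobiology import lethality_exponent, lq_survival


def grid_with(t_end, *anchors, n=801):
    return np.unique(np.concatenate([np.linspace(0.0, t_end, n), list(anchors)]))


class TestTreatmentSpec:
    def test_eta_cl(self):
        assert TreatmentSpec(dose=1, t_r=0, t_cl=13.0).eta_cl == pytest.approx(LN2 / 13)

    def test_infinite_clearance(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            spec = TreatmentSpec(dose=1, t_r=0, tau_rad=30.0, t_cl=float("inf"))
        assert spec.eta_cl == 0.0

    def test_tau_outside_usual_range_warns(self):
        with pytest.warns(UserWarning, match="tau_rad"):
            TreatmentSpec(dose=1, t_r=0, tau_rad=30.0, t_cl=5.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dose": -1, "t_r": 0, "t_cl": 5},
            {"dose": 1, "t_r": -1, "t_cl": 5},
            {"dose": 1, "t_r": 0, "tau_rad": 0, "t_cl": 5},
            {"dose": 1, "t_r": 0, "t_cl": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TreatmentSpec(**kwargs)


class TestCaseConfigIO:
    def test_round_trip(self, clinical_configs):
        for c in clinical_configs:
            assert CaseConfig.from_dict(c.to_dict()) == c

    def test_json_file_round_trip(self, simple_config, tmp_path):
        path = tmp_path / "case.json"
        simple_config.to_json(path)
        assert CaseConfig.from_json(path) == simple_config

    def test_missing_key_raises(self):
        with pytest.raises(ValueError, match="missing"):
            CaseConfig.from_dict({"label": "x"})

    def test_override_lambda_r(self, simple_config):
        c = CaseConfig(
            label="o",
            growth=simple_config.growth,
            radio=simple_config.radio,
            treatment=simple_config.treatment,
            td_at_treatment=5.0,
        )
        assert c.lambda_r() == pytest.approx(LN2 / 5.0)
        assert simple_config.lambda_r() == pytest.approx(
            simple_config.growth.lam0
            * math.exp(-simple_config.growth.decay_rate * simple_config.treatment.t_r)
        )


class TestSimulateNoDose:
    def test_matches_gompertz_exactly(self, rat_configs, dense_grid):
        control = rat_configs[0]
        assert control.treatment.dose == 0.0
        traj = simulate(control, dense_grid)
        assert np.array_equal(traj.v_nd, np.zeros_like(dense_grid))
        assert np.allclose(traj.v_t, gompertz_volume(dense_grid, control.growth), rtol=1e-15)

    def test_numeric_matches_gompertz(self, rat_configs):
        control = rat_configs[0]
        t = np.linspace(0, 60, 61)
        traj = integrate_numeric(control, t)
        closed = gompertz_volume(t, control.growth)
        assert np.max(np.abs(traj.v_total - closed) / closed) < 1e-6


class TestSimulateProposed:
    def test_case1_r40_from_raw_trajectory(self, clinical_configs):
        c = clinical_configs[0]
        tr = c.treatment
        times = grid_with(tr.t_r + 40.0, tr.t_r, tr.t_r + 40.0)
        traj = simulate(c, times)
        i_r = np.searchsorted(times, tr.t_r)
        i_40 = np.searchsorted(times, tr.t_r + 40.0)
        ratio = traj.v_total[i_40] / traj.v_total[i_r]
        assert ratio == pytest.approx(0.16, rel=0.10)

    def test_pure_death_equals_lq_survival(self):
        # lambda_R = 0, tau_rad = 3 T_m: V_T ratio is exactly exp(-chi)
        radio = RadiobiologyConstants(alpha=0.30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            c = CaseConfig(
                label="pure-death",
                growth=GrowthParams(v0=1.0, td0=4.0, theta=0.9),
                radio=radio,
                treatment=TreatmentSpec(dose=10.0, t_r=5.0, tau_rad=30.0, t_cl=1e9),
                td_at_treatment=float("inf"),
            )
        times = np.array([0.0, 5.0, 35.0])
        traj = simulate(c, times)
        chi = lethality_exponent(10.0, radio)
        expected = math.exp(-chi)
        # t_cl finite but enormous: V_ND contributes, V_T ratio is the target
        assert traj.v_t[2] / traj.v_t[1] == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_phase_boundaries(self, simple_config):
        tr = simple_config.treatment
        eps = 1e-9
        times = np.unique(
            np.array(
                [
                    tr.t_r - eps, tr.t_r, tr.t_r + eps,
                    tr.t_r + tr.tau_rad - eps, tr.t_r + tr.tau_rad,
                    tr.t_r + tr.tau_rad + eps,
                ]
            )
        )
        traj = simulate(simple_config, times)
        v = traj.v_total
        assert v[1] == pytest.approx(v[0], rel=1e-7)
        assert v[2] == pytest.approx(v[1], rel=1e-7)
        assert v[4] == pytest.approx(v[3], rel=1e-7)
        assert v[5] == pytest.approx(v[4], rel=1e-7)

    def test_vnd_zero_before_treatment(self, simple_config, dense_grid):
        traj = simulate(simple_config, dense_grid)
        pre = dense_grid < simple_config.treatment.t_r
        assert np.all(traj.v_nd[pre] == 0.0)
        post = dense_grid >= simple_config.treatment.t_r + 1e-9
        assert np.all(traj.v_nd[post] > 0.0)

    def test_vnd_vanishes_long_after(self, simple_config):
        times = np.array([0.0, 30.0, 1000.0])
        traj = simulate(simple_config, times)
        assert traj.v_nd[2] < 1e-12

    def test_lambda_frozen_in_window(self, simple_config, dense_grid):
        traj = simulate(simple_config, dense_grid)
        tr = simple_config.treatment
        mid = (dense_grid >= tr.t_r) & (dense_grid < tr.t_r + tr.tau_rad)
        assert np.allclose(traj.lam[mid], simple_config.lambda_r(), rtol=1e-15)

    def test_tiny_window_converges_to_no_effect(self, simple_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tiny = TreatmentSpec(
                dose=simple_config.treatment.dose,
                t_r=simple_config.treatment.t_r,
                tau_rad=1e-8,
                t_cl=simple_config.treatment.t_cl,
            )
        c = CaseConfig(
            label="tiny",
            growth=simple_config.growth,
            radio=simple_config.radio,
            treatment=tiny,
        )
        t = np.linspace(0, 60, 121)
        traj = simulate(c, t)
        unirr = gompertz_volume(t, c.growth)
        assert np.max(np.abs(traj.v_total - unirr) / unirr) < 1e-6

    def test_grid_refinement_invariance(self, simple_config):
        probe = np.array([0.0, 10.0, 22.0, 25.0, 40.0, 70.0])
        coarse = simulate(simple_config, probe)
        fine_grid = np.unique(np.concatenate([np.linspace(0, 70, 7001), probe]))
        fine = simulate(simple_config, fine_grid)
        idx = np.searchsorted(fine_grid, probe)
        assert np.allclose(coarse.v_total, fine.v_total[idx], rtol=1e-14)

    def test_t_r_outside_span_raises(self, simple_config):
        with pytest.raises(ValueError, match="outside"):
            simulate(simple_config, np.linspace(0, 10, 11))

    @pytest.mark.parametrize(
        "bad_times", [np.array([]), np.array([[0.0, 1.0]]), np.array([0.0, 0.0, 1.0]), np.array([-1.0, 30.0])]
    )
    def test_bad_grid_raises(self, simple_config, bad_times):
        with pytest.raises(ValueError):
            simulate(simple_config, bad_times)


class TestPhase2ClosedForm:
    def test_dt_zero_continuity(self):
        v_t, v_nd = phase2_closed_form(3.0, 0.05, 0.7, 0.3, 0.1, 0.0)
        assert v_t == 3.0
        assert v_nd == 0.0

    def test_case1_coefficients(self):
        # a = 0.02126*0.445 - 0.555 = -0.5455; exp(-4.364) ~ 0.0127
        v_t, _ = phase2_closed_form(1.0, 0.02126, 0.445, 0.555, 0.05, 8.0)
        assert v_t == pytest.approx(math.exp(-4.364), rel=1e-3)
        assert v_t == pytest.approx(0.0127, rel=0.01)

    def test_degenerate_limit_matches_ode(self):
        # a == -eta exactly: lam_r = 0, p arbitrary, g = eta
        g = eta = 0.25
        v0 = 2.0
        sol = solve_ivp(
            lambda t, y: [-g * y[0], g * y[0] - eta * y[1]],
            (0.0, 6.0),
            [v0, 0.0],
            rtol=1e-12,
            atol=1e-14,
            dense_output=True,
        )
        for dt in (0.5, 2.0, 6.0):
            v_t, v_nd = phase2_closed_form(v0, 0.0, 1.0, g, eta, dt)
            ref_t, ref_nd = sol.sol(dt)
            assert v_t == pytest.approx(ref_t, rel=1e-8)
            assert v_nd == pytest.approx(ref_nd, rel=1e-8)

    def test_generic_matches_ode(self):
        lam_r, p, g, eta = 0.021, 0.445, 0.555, 0.0533
        a = lam_r * p - g
        sol = solve_ivp(
            lambda t, y: [a * y[0], g * y[0] - eta * y[1]],
            (0.0, 8.0),
            [1.0, 0.0],
            rtol=1e-12,
            atol=1e-15,
            dense_output=True,
        )
        v_t, v_nd = phase2_closed_form(1.0, lam_r, p, g, eta, 8.0)
        ref_t, ref_nd = sol.sol(8.0)
        assert v_t == pytest.approx(ref_t, rel=1e-9)
        assert v_nd == pytest.approx(ref_nd, rel=1e-9)

    def test_vectorized(self):
        dt = np.array([0.0, 1.0, 4.0])
        v_t, v_nd = phase2_closed_form(1.0, 0.02, 0.8, 0.4, 0.07, dt)
        assert v_t.shape == dt.shape
        assert v_nd[0] == 0.0


class TestStandardModel:
    def test_no_dose_no_jump(self, rat_configs, dense_grid):
        control = rat_configs[0]
        traj = simulate_standard_model(control, dense_grid)
        assert np.allclose(traj.v_total, gompertz_volume(dense_grid, control.growth), rtol=1e-14)

    def test_jump_ratio_is_survival(self, rat_configs):
        c = rat_configs[1]  # 10 Gy, alpha 0.30 -> chi 6
        tr = c.treatment
        times = grid_with(40.0, tr.t_r - 1e-9, tr.t_r)
        traj = simulate_standard_model(c, times)
        i = np.searchsorted(times, tr.t_r)
        ratio = traj.v_t[i] / traj.v_t[i - 1]
        assert ratio == pytest.approx(math.exp(-6.0), rel=1e-6)
        assert ratio == pytest.approx(2.479e-3, rel=1e-3)

    def test_total_conserved_across_jump(self, rat_configs):
        c = rat_configs[4]
        tr = c.treatment
        times = grid_with(40.0, tr.t_r - 1e-9, tr.t_r)
        traj = simulate_standard_model(c, times)
        i = np.searchsorted(times, tr.t_r)
        assert traj.v_total[i] == pytest.approx(traj.v_total[i - 1], rel=1e-7)

    def test_equivalence_to_proposed_pure_death(self):
        # lambda_R = 0, eta_cl = 0, tau_rad = 3 T_m: proposed surviving V_T
        # equals the standard model's post-jump V_T exactly
        radio = RadiobiologyConstants(alpha=0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            treat = TreatmentSpec(dose=20.0, t_r=10.0, tau_rad=30.0, t_cl=float("inf"))
        c = CaseConfig(
            label="x",
            growth=GrowthParams(v0=1.0, td0=5.0, theta=0.7),
            radio=radio,
            treatment=treat,
            td_at_treatment=float("inf"),
        )
        times = np.array([0.0, 10.0, 40.0])
        proposed = simulate(c, times)
        s = lq_survival(20.0, radio)
        assert proposed.v_t[2] / proposed.v_t[1] == pytest.approx(s, rel=1e-12)


class TestNumericEquivalence:
    def test_all_fixture_configs(self, all_configs):
        times = np.linspace(0.0, 200.0, 201)
        for c in all_configs:
            closed = simulate(c, times)
            numeric = integrate_numeric(c, times)
            dev = np.max(np.abs(closed.v_total - numeric.v_total) / closed.v_total)
            assert dev < 1e-6, f"{c.label}: deviation {dev:.2e}"

    def test_tolerance_invariance(self, simple_config):
        times = np.linspace(0.0, 80.0, 81)
        a = integrate_numeric(simple_config, times, rtol=1e-10)
        b = integrate_numeric(simple_config, times, rtol=1e-12, atol=1e-18)
        assert np.allclose(a.v_total, b.v_total, rtol=1e-8)

    def test_grid_not_containing_boundaries(self, simple_config):
        # phase boundaries (20, 28) fall between grid points
        times = np.array([0.0, 7.3, 19.9, 21.7, 27.9, 33.3, 61.1])
        closed = simulate(simple_config, times)
        numeric = integrate_numeric(simple_config, times)
        assert np.allclose(closed.v_total, numeric.v_total, rtol=1e-7)


class TestTrajectory:
    def test_csv_columns(self, simple_config, tmp_path):
        import pandas as pd

        traj = simulate(simple_config, np.linspace(0, 60, 13))
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == [
            "t_days", "v_t_cm3", "v_nd_cm3", "lambda_per_day", "v_total_cm3",
        ]
        assert np.allclose(df["v_total_cm3"], df["v_t_cm3"] + df["v_nd_cm3"])

    def test_invalid_arrays(self):
        from radkin.simulator import Trajectory

        with pytest.raises(ValueError):
            Trajectory(times=[0, 1], v_t=[1], v_nd=[0, 0], lam=[0.1, 0.1])
        with pytest.raises(ValueError):
            Trajectory(times=[1, 0], v_t=[1, 1], v_nd=[0, 0], lam=[0.1, 0.1])
        with pytest.raises(ValueError):
            Trajectory(times=[0, 1], v_t=[1, -1], v_nd=[0, 0], lam=[0.1, 0.1])
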