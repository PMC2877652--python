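"""Integration, scenario-editing and metric tests."""

import numpy as np
import pytest

from lnflare import (
    InvalidParameterError,
    RateOverride,
    ScenarioSpec,
    StateVector,
    TherapyEdit,
    Trajectory,
    apply_scenario,
    default_grid,
    run_scenarios,
    simulate,
    summarize,
)
from reference import max_rel_supnorm_error, rk4_piecewise


class TestSimulate:
    def test_linear_anti_inflammatory_closed_form(
        self, decoupled_params, single_interval_schedule
    ):
        # with all couplings off, A' = s_a - mu_a A has the closed form
        # A(t) = s_a/mu_a + (A0 - s_a/mu_a) exp(-mu_a t)
        sched = single_interval_schedule(0.0, 5.0, s_a=2.2)
        t = np.linspace(0, 5, 51)
        traj = simulate(decoupled_params, sched, StateVector(0, 0, 0, 0.1), t)
        expected = 1.0 + (0.1 - 1.0) * np.exp(-2.2 * t)
        assert np.allclose(traj.A, expected, rtol=1e-6, atol=1e-8)

    def test_exponential_decay_of_each_state(
        self, decoupled_params, single_interval_schedule
    ):
        sched = single_interval_schedule(0.0, 50.0)
        t = np.linspace(0, 50, 101)
        traj = simulate(decoupled_params, sched, StateVector(1, 2, 3, 0.5), t)
        assert np.allclose(traj.I, 1.0, rtol=1e-7)  # no clearance without P... I is constant
        assert np.allclose(traj.P, 2 * np.exp(-0.06 * t), rtol=1e-6)
        assert np.allclose(traj.D, 3 * np.exp(-0.04 * t), rtol=1e-6)
        assert np.allclose(traj.A, 0.5 * np.exp(-2.2 * t), rtol=1e-6, atol=1e-10)

    def test_semigroup_property(self, patient_416):
        """Stopping at the flare and restarting from the endpoint state must
        reproduce the one-shot solution."""
        params, schedule, state0 = patient_416
        grid = default_grid(schedule)
        full = simulate(params, schedule, state0, grid)
        first = simulate(params, schedule, state0, grid[grid <= 0.0])
        mid = StateVector.from_array(first.states[-1])
        second = simulate(params, schedule, mid, grid[grid >= 0.0])
        stitched = np.vstack([first.states, second.states[1:]])
        assert np.allclose(stitched, full.states, rtol=1e-6, atol=1e-9)

    def test_matches_rk4_reference(self, patient_416):
        """Adaptive piecewise solver agrees with an independently coded
        fixed-step RK4 at the breakpoints to 1e-5 relative sup-norm."""
        params, schedule, state0 = patient_416
        ref_t, ref_y = rk4_piecewise(
            params.to_dict(),
            schedule.breakpoints,
            [(lv.s_i, lv.s_id, lv.s_a) for lv in schedule.intervals],
            state0.to_array(),
            h=0.01,
        )
        traj = simulate(params, schedule, state0, ref_t)
        assert max_rel_supnorm_error(ref_y, traj.states) < 1e-5

    def test_output_includes_interior_breakpoints(self, patient_416):
        params, schedule, state0 = patient_416
        traj = simulate(params, schedule, state0, np.array([-180.0, 120.0]))
        for bp in schedule.breakpoints:
            assert bp in traj.times

    def test_grid_outside_span_rejected(self, patient_416):
        params, schedule, state0 = patient_416
        with pytest.raises(Exception):
            simulate(params, schedule, state0, np.array([-200.0, 0.0]))

    def test_grid_refinement_converges(self, patient_416):
        params, schedule, state0 = patient_416
        m1 = summarize(simulate(params, schedule, state0, default_grid(schedule, 0.5)))
        m2 = summarize(simulate(params, schedule, state0, default_grid(schedule, 0.25)))
        for name in ("peak_P", "peak_D", "auc_P", "auc_D"):
            a, b = getattr(m1, name), getattr(m2, name)
            assert abs(a - b) / max(abs(b), 1e-12) < 1e-3


class TestApplyScenario:
    def test_empty_edit_is_identity(self, patient_416):
        params, schedule, _ = patient_416
        s2, p2 = apply_scenario(schedule, params, ScenarioSpec("noop"))
        assert s2 == schedule and p2 == params

    def test_therapy_edit_values_and_immutability(self, patient_416):
        params, schedule, _ = patient_416
        sc = ScenarioSpec(
            "maintain", (TherapyEdit(-60.0, 0.0, s_i=0.001, s_id=0.003, s_a=0.1),)
        )
        s2, p2 = apply_scenario(schedule, params, sc)
        lv = s2.levels_at(-30.0)
        assert (lv.s_i, lv.s_id, lv.s_a) == (0.001, 0.003, 0.1)
        # outside the edit range: unchanged
        assert s2.levels_at(-100.0) == schedule.levels_at(-100.0)
        assert s2.levels_at(10.0) == schedule.levels_at(10.0)
        # original untouched
        assert schedule.levels_at(-30.0).s_a == 0.05
        assert p2 == params

    def test_edit_splits_mid_interval(self, patient_416):
        params, schedule, _ = patient_416
        sc = ScenarioSpec("late", (TherapyEdit(-30.0, -20.0, s_a=9.0),))
        s2, _ = apply_scenario(schedule, params, sc)
        assert s2.levels_at(-25.0).s_a == 9.0
        assert s2.levels_at(-40.0).s_a == schedule.levels_at(-40.0).s_a
        assert s2.levels_at(-15.0).s_a == schedule.levels_at(-15.0).s_a

    def test_rate_override(self, patient_416):
        params, schedule, _ = patient_416
        s2, p2 = apply_scenario(
            schedule, params, ScenarioSpec("halflife", (RateOverride("mu_a", 1.1),))
        )
        assert p2.mu_a == 1.1 and params.mu_a == 2.2
        assert s2 == schedule

    def test_invalid_edits_rejected(self, patient_416):
        params, schedule, _ = patient_416
        with pytest.raises(InvalidParameterError):
            apply_scenario(
                schedule, params, ScenarioSpec("bad", (RateOverride("nope", 1.0),))
            )
        with pytest.raises(InvalidParameterError):
            apply_scenario(
                schedule, params,
                ScenarioSpec("bad", (TherapyEdit(-500.0, -400.0, s_a=1.0),)),
            )


class TestSummarize:
    def _traj(self, t, P, D, patient_416):
        params, schedule, _ = patient_416
        states = np.column_stack([np.zeros_like(t), P, D, np.zeros_like(t)])
        return Trajectory(np.asarray(t, float), states, params, schedule)

    def test_constant_profile(self, patient_416):
        t = np.linspace(-10, 10, 21)
        m = summarize(self._traj(t, np.full(21, 3.0), np.full(21, 1.0), patient_416),
                      baseline_P=1.0, baseline_D=1.0)
        assert m.peak_P == 3.0
        assert m.auc_P == pytest.approx((3.0 - 1.0) * 20.0)
        assert m.auc_D == pytest.approx(0.0)

    def test_single_point(self, patient_416):
        m = summarize(self._traj([0.0], [2.0], [1.0], patient_416))
        assert m.peak_P == 2.0 and m.auc_P == 0.0

    def test_triangular_profile_trapezoid(self, patient_416):
        # hand trapezoid: rise 0->4 over 2 days, fall 4->0 over 2 days,
        # baseline 0 -> area = 0.5 * base(4) * height(4) = 8
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        P = np.array([0.0, 2.0, 4.0, 2.0, 0.0])
        m = summarize(self._traj(t, P, P, patient_416), baseline_P=0.0, baseline_D=0.0)
        assert m.auc_P == pytest.approx(8.0)
        assert m.peak_P == 4.0 and m.t_peak_P == 2.0


class TestScenarioRuns:
    def test_baseline_always_first(self, patient_416):
        params, schedule, state0 = patient_416
        res = run_scenarios(params, schedule, state0, [], default_grid(schedule, 2.0))
        assert list(res) == ["baseline"]
        direct = summarize(
            simulate(params, schedule, state0, default_grid(schedule, 2.0))
        )
        assert res["baseline"][1] == direct

    def test_sustained_anti_inflammatory_boost_never_raises_peaks(
        self, all_patients
    ):
        """Doubling s_a from any start time through the end of the cycle
        must not increase peak P or D. (A boost on an isolated interval
        that lapses before flare is *not* monotone: suppressed inflammation
        also suppresses immune-complex clearance, and the accumulated
        complexes can drive a higher later peak.)"""
        for params, schedule, state0 in all_patients.values():
            grid = default_grid(schedule, 2.0)
            base = summarize(simulate(params, schedule, state0, grid))
            for t_from in (-180.0, -60.0, 0.0):
                boosted = schedule
                for idx in range(schedule.n_intervals):
                    if schedule.breakpoints[idx] >= t_from:
                        boosted = boosted.with_interval(
                            idx, s_a=schedule.intervals[idx].s_a * 2.0
                        )
                m = summarize(simulate(params, boosted, state0, grid))
                assert m.peak_P <= base.peak_P * (1 + 1e-9)
                assert m.peak_D <= base.peak_D * (1 + 1e-9)

    def test_weaker_immune_complex_influx_never_raises_damage(self, all_patients):
        for params, schedule, state0 in all_patients.values():
            grid = default_grid(schedule, 2.0)
            base = summarize(simulate(params, schedule, state0, grid))
            halved = schedule
            for idx in range(schedule.n_intervals):
                lv = schedule.intervals[idx]
                halved = halved.with_interval(idx, s_i=lv.s_i / 2, s_id=lv.s_id / 2)
            m = summarize(simulate(params, halved, state0, grid))
            assert m.peak_D <= base.peak_D * (1 + 1e-9)

    def test_longer_proinflammatory_halflife_never_lowers_peak_P(self, all_patients):
        for params, schedule, state0 in all_patients.values():
            grid = default_grid(schedule, 2.0)
            base = summarize(simulate(params, schedule, state0, grid))
            m = summarize(
                simulate(params.replace(mu_p=params.mu_p / 2), schedule, state0, grid)
            )
            assert m.peak_P >= base.peak_P * (1 - 1e-9)
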