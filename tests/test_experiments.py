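"""Protocol-level behaviour: goal generation, schedules, caching, the
cursor-rotation bookkeeping and the adaptation-speed statistic."""

import copy
import dataclasses

import numpy as np
import pytest

from motorloop import kinematics
from motorloop.experiments import (AdaptationSchedule, MotorModel,
                                   cache_actions, generate_goals,
                                   initial_hand_position, pretrain_bg,
                                   run_adaptation, run_reaching,
                                   trials_to_half_error)


class TestGoals:
    def test_minimum_distance_and_reachability(self, rng):
        goals = generate_goals(6, rng)
        start = initial_hand_position()
        for g in goals:
            assert np.linalg.norm(g.position - start) >= 0.5
            # reachable by construction: the stored angles produce the position
            assert kinematics.forward_kinematics(g.source_angles) == pytest.approx(
                g.position)

    def test_seeded_determinism(self):
        a = generate_goals(4, np.random.default_rng(11))
        b = generate_goals(4, np.random.default_rng(11))
        for x, y in zip(a, b):
            assert np.array_equal(x.position, y.position)

    def test_rejects_empty_request(self, rng):
        with pytest.raises(ValueError):
            generate_goals(0, rng)


class TestSchedule:
    def test_phase_windows(self):
        s = AdaptationSchedule(condition="rotation_plus_strategy",
                               baseline_trials=10, instruction_delay=2,
                               perturbed_trials=20,
                               strategy_off_to_rotation_off=5,
                               washout_trials=8)
        assert not s.rotation_active(9) and s.rotation_active(10)
        assert s.rotation_active(34) and not s.rotation_active(35)
        assert not s.instruction_active(11) and s.instruction_active(12)
        assert s.instruction_active(29) and not s.instruction_active(30)
        assert s.n_trials == 43

    def test_strategy_condition_has_no_rotation(self):
        s = AdaptationSchedule(condition="strategy")
        assert not any(s.rotation_active(t) for t in range(s.n_trials))
        assert s.instruction_active(s.instruction_start)

    def test_rotation_condition_has_no_instruction(self):
        s = AdaptationSchedule(condition="rotation")
        assert not any(s.instruction_active(t) for t in range(s.n_trials))

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            AdaptationSchedule(condition="both")
        with pytest.raises(ValueError):
            AdaptationSchedule(baseline_trials=-1)


class TestCaching:
    def test_cached_parameters_match_action_readout(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        goals = generate_goals(2, np.random.default_rng(5))
        cache_actions(bundle.model, goals)
        for g in goals:
            a = bundle.model.cached_actions[g.id]
            assert np.array_equal(bundle.model.cached_params[g.id],
                                  bundle.bg.library.exact_params(a))


@pytest.fixture(scope="module")
def ablated_runs(unit_bundle):
    """Same seed, ablated cerebellum, rotation on vs off."""
    goals = generate_goals(2, np.random.default_rng(3))
    runs = {}
    for cond in ("rotation", "strategy"):
        bundle = copy.deepcopy(unit_bundle)
        bundle.model.cerebellum = None
        sched = AdaptationSchedule(condition=cond, baseline_trials=3,
                                   instruction_delay=10**6,  # never instruct
                                   perturbed_trials=6,
                                   strategy_off_to_rotation_off=0,
                                   washout_trials=3)
        runs[cond] = (sched, run_adaptation(bundle.model, sched, goals))
    return runs


class TestRotationBookkeeping:

    def test_rotation_never_alters_the_arm(self, ablated_runs):
        (_, rot), (_, no_rot) = ablated_runs["rotation"], ablated_runs["strategy"]
        for a, b in zip(rot, no_rot):
            assert np.array_equal(a.joint_angles, b.joint_angles)
            assert np.array_equal(a.hand_position, b.hand_position)

    def test_display_equals_hand_when_rotation_off(self, ablated_runs):
        sched, recs = ablated_runs["rotation"]
        for r in recs:
            if sched.rotation_active(r.trial):
                assert not np.allclose(r.displayed_position, r.hand_position)
            else:
                assert np.array_equal(r.displayed_position, r.hand_position)

    def test_displayed_rotation_angle_is_exact(self, ablated_runs):
        sched, recs = ablated_runs["rotation"]
        start = initial_hand_position()
        goals = generate_goals(2, np.random.default_rng(3))
        axis = np.cross(goals[0].position - start, goals[1].position - start)
        for r in recs:
            if sched.rotation_active(r.trial):
                ang_h = kinematics.angular_error(start, r.hand_position,
                                                 goals[r.goal_id].position, axis)
                ang_d = kinematics.angular_error(start, r.displayed_position,
                                                 goals[r.goal_id].position, axis)
                assert (ang_d - ang_h + 180) % 360 - 180 == pytest.approx(
                    sched.rotation_deg, abs=1e-6)


class TestInstruction:
    def test_instruction_changes_only_the_motor_goal(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        bundle.model.cerebellum = None
        goals = generate_goals(2, np.random.default_rng(3))
        sched = AdaptationSchedule(condition="strategy", baseline_trials=2,
                                   instruction_delay=0, perturbed_trials=4,
                                   strategy_off_to_rotation_off=0,
                                   washout_trials=2)
        recs = run_adaptation(bundle.model, sched, goals)
        for r in recs:
            if sched.instruction_active(r.trial):
                assert r.motor_goal_id == r.goal_id + 2
            else:
                assert r.motor_goal_id == r.goal_id


class TestReaching:
    def test_ablated_model_is_flat_across_trials(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        bundle.model.cerebellum = None
        goals = generate_goals(2, np.random.default_rng(9))
        recs = run_reaching(bundle.model, goals, 8)
        per_goal = {0: set(), 1: set()}
        for r in recs:
            per_goal[r.goal_id].add(round(r.error, 12))
        # no adaptive component: every visit to a goal repeats the same error
        assert all(len(v) == 1 for v in per_goal.values())

    def test_goal_cycling(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        bundle.model.cerebellum = None
        goals = generate_goals(3, np.random.default_rng(9))
        recs = run_reaching(bundle.model, goals, 6)
        assert [r.goal_id for r in recs] == [0, 1, 2, 0, 1, 2]


class TestCerebellumAloneReadouts:
    def test_direct_readout_maps_outputs_to_angles(self):
        from motorloop.cerebellum import Reservoir, ReservoirParams, outputs_to_angles
        res = Reservoir(ReservoirParams(n_units=40, n_outputs=6), 1,
                        np.random.default_rng(2))
        model = MotorModel(bg=None, cerebellum=res, readout="direct")
        out = res.run_trial(0, learn=False)
        _, angles = model.movement_cerebellum_alone(out)
        assert angles == pytest.approx(
            model.fixed.U_ref + outputs_to_angles(out, model.fixed.Amp))

    def test_unknown_readout_rejected(self):
        with pytest.raises(ValueError):
            MotorModel(readout="spline")


class TestPretraining:
    def test_without_learning_never_converges(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        bg = bundle.bg
        # disable all plasticity: novelty weights and corticostriatal weights
        bg.plasticity_step = lambda: None
        res = pretrain_bg(bundle.model, np.random.default_rng(0),
                          max_trials=12, min_trials=1)
        assert not res.converged
        assert res.n_trials == 12

    def test_smoke_convergence_and_trace_shape(self, unit_bundle):
        bundle = copy.deepcopy(unit_bundle)
        res = pretrain_bg(bundle.model, np.random.default_rng(1),
                          max_trials=60, min_trials=5)
        assert res.distances.shape == (res.n_trials,)
        assert np.all(res.distances >= 0)


class TestAdaptationSpeedStatistic:
    def test_constructed_decay_gives_known_crossing(self):
        # moving-average window 10; error halves exactly at trial 30 post-onset
        err = np.concatenate([np.full(20, 5.0), np.full(30, 40.0), np.full(60, 10.0)])
        speed = trials_to_half_error(err, onset=20, window=10)
        # oracle: first window mean is 40; the smoothed trace dips below 20
        # once 7 of the 10 averaged trials are at 10.0 -> index 20 + 7 = 27
        smooth = np.convolve(np.abs(err[20:]), np.ones(10) / 10, "valid")
        expected = np.nonzero(smooth < smooth[0] / 2)[0][0]
        assert speed == expected == 27

    def test_flat_error_never_halves(self):
        err = np.full(80, 30.0)
        assert trials_to_half_error(err, onset=10) == np.inf
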