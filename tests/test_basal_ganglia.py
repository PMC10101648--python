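"""Rate-loop fixed points, goal encoding, selection semantics, plasticity
sign structure and the novelty dopamine signal."""

import numpy as np
import pytest

from motorloop.basal_ganglia import ActionLibrary, BGNetwork, BGParams
from motorloop.cerebellum import param_grid_bounds

QUIET = dict(noise_amplitude=0.0, n_actions=8, n_premotor=40)


def quiet_net(seed=0, **kw):
    return BGNetwork(BGParams(**{**QUIET, **kw}), np.random.default_rng(seed))


class TestRateFixedPoints:
    def test_resting_loop_matches_closed_forms(self):
        net = quiet_net()
        net.settle(simulate_ms=200.0)  # 20 tau, dynamic relaxation
        p = net.p
        assert net.r_snr == pytest.approx(np.full(8, p.B_snr), abs=1e-6)
        expected_thal = p.B_thalamus - p.w_snr_thal * p.B_snr  # 0.24
        assert expected_thal == pytest.approx(0.24)
        assert net.r_thal == pytest.approx(np.full(8, expected_thal), abs=1e-6)
        assert net.r_ctx == pytest.approx(np.zeros(8), abs=1e-6)
        assert net.DA == pytest.approx(p.B_DA, abs=1e-6)

    def test_snr_under_unit_striatal_drive(self):
        net = quiet_net()
        net.settle()
        for _ in range(300):
            net.r_str[:] = 1.0
            net.rate_step()
        # mp = B_snr - w_str_snr * 1 = 1.1 - 0.8
        assert net.mp_snr == pytest.approx(np.full(8, 0.3), abs=1e-6)

    def test_analytic_settle_agrees_with_dynamic_settle(self):
        net = quiet_net(seed=3)
        net.settle()
        analytic = (net.r_str.copy(), net.r_snr.copy(), net.r_thal.copy(),
                    net.r_ctx.copy())
        net2 = quiet_net(seed=3)
        net2.settle(simulate_ms=300.0)
        for a, b in zip(analytic, (net2.r_str, net2.r_snr, net2.r_thal, net2.r_ctx)):
            assert a == pytest.approx(b, abs=1e-6)

    def test_rates_are_rectified(self, rng):
        net = quiet_net()
        net.mp_ctx[:] = -1.0
        net.rate_step()
        assert np.all(net.r_ctx >= 0)
        assert np.all(net.r_snr >= 0)


class TestGoalEncoding:
    def test_gaussian_tuning_peak_and_tail(self):
        net = quiet_net()
        goal = net.premotor_positions[5]
        net.encode_goal(goal)
        assert net.b_pre[5] == pytest.approx(1.0)
        far = goal + np.array([10.0, 0, 0])
        net.encode_goal(far)
        assert np.all(net.b_pre < 1e-6)

    def test_equidistant_cells_get_equal_baselines(self):
        net = quiet_net()
        net.premotor_positions[0] = [0.2, 0.0, 0.0]
        net.premotor_positions[1] = [-0.2, 0.0, 0.0]
        net.encode_goal(np.zeros(3))
        assert net.b_pre[0] == pytest.approx(net.b_pre[1])

    def test_rejects_non_finite_goal(self):
        with pytest.raises(ValueError):
            quiet_net().encode_goal(np.array([np.nan, 0, 0]))


class TestSelection:
    def test_untrained_network_selects_randomly(self):
        net = quiet_net(seed=1)
        net.settle()
        action = net.select_action(np.array([0.2, 0.2, 0.1]), stabilise=False)
        assert net.last_selection_random
        assert 0 <= action < net.p.n_actions

    def test_clamp_is_exclusive(self):
        net = quiet_net(seed=2)
        net.settle()
        a = net.select_action(np.array([0.1, 0.3, -0.2]))
        assert net.r_ctx[a] == 1.0
        others = np.delete(net.r_ctx, a)
        assert np.all(others < 1.0)

    def test_learned_outcome_recalls_its_action(self, unit_bundle):
        """After binding an outcome to an executed action, presenting that
        outcome as the goal drives the cortex above threshold and re-selects
        the producing action."""
        import copy
        bg = copy.deepcopy(unit_bundle.bg)
        outcome = bg.premotor_positions[3]  # guaranteed premotor coverage
        bg.settle()
        a = bg.select_action(outcome, force_random=True)
        for _ in range(3):
            bg.learn_trial(outcome)
            bg.settle()
            bg.clamp = a
            bg.mp_ctx[a] = 1.0
            bg.r_ctx[a] = 1.0
        bg.settle()
        chosen = bg.select_action(outcome, stabilise=False)
        assert not bg.last_selection_random
        assert chosen == a


class TestDecode:
    def test_single_active_cell_reads_its_preferred_value(self, rng):
        lib = ActionLibrary(4, 21, rng)
        rates = np.zeros((24, 21))
        rates[:, 7] = 1.0
        decoded = lib.decode(rates).ravel()
        assert decoded == pytest.approx(lib.preferred[:, 7])

    def test_uniform_activity_reads_interval_mean(self, rng):
        lib = ActionLibrary(4, 21, rng)
        decoded = lib.decode(np.ones((24, 21))).ravel()
        assert decoded == pytest.approx(lib.preferred.mean(axis=1))

    def test_zero_activity_falls_back_to_midpoint(self, rng):
        lib = ActionLibrary(4, 21, rng)
        lo, hi = param_grid_bounds()
        decoded = lib.decode(np.zeros((24, 21))).ravel()
        assert decoded == pytest.approx((lo + hi) / 2)

    def test_decode_is_always_within_clamp(self, rng):
        lib = ActionLibrary(4, 21, rng)
        lo, hi = param_grid_bounds()
        for _ in range(10):
            decoded = lib.decode(rng.uniform(0, 1, (24, 21))).ravel()
            assert np.all(decoded >= lo) and np.all(decoded <= hi)


class TestDopamine:
    def test_gate_closed_relaxes_to_baseline(self):
        net = quiet_net()
        net.DA = 0.9
        net.P = 0.0
        for _ in range(200):
            net.dopamine_step()
        assert net.DA == pytest.approx(0.1, abs=1e-6)

    def test_gate_open_unpredicted_relaxes_to_burst(self):
        net = quiet_net()
        net.P = 1.0
        net.r_str[:] = 0.0
        for _ in range(200):
            net.dopamine_step()
        assert net.DA == pytest.approx(1.1, abs=1e-6)

    def test_fully_predicted_outcome_silences_burst(self):
        net = quiet_net()
        net.P = 1.0
        net.W_str_da[:] = 1.0
        for _ in range(200):
            net.r_str[:] = 1.0 / net.p.n_actions  # sum w r = 1
            net.dopamine_step()
        assert net.DA == pytest.approx(0.1, abs=1e-6)

    def test_novelty_burst_shrinks_over_outcome_repetitions(self, unit_bundle):
        import copy
        bg = copy.deepcopy(unit_bundle.bg)
        outcome = bg.premotor_positions[7]  # guaranteed premotor coverage
        bg.settle()
        a = bg.select_action(outcome, force_random=True)
        peaks = []
        for _ in range(4):
            peaks.append(bg.learn_trial(outcome))
            bg.settle()
            bg.clamp = a
            bg.mp_ctx[a] = 1.0
            bg.r_ctx[a] = 1.0
        assert all(x >= y - 1e-6 for x, y in zip(peaks, peaks[1:]))  # non-increasing
        assert peaks[0] > 0.5                     # first exposure: strong burst
        assert peaks[-1] < peaks[0] / 2           # familiar outcome: silenced
        assert peaks[-1] == pytest.approx(bg.p.B_DA, abs=0.1)


class TestCorticostriatalPlasticity:
    def test_baseline_dopamine_only_depresses(self):
        net = quiet_net()
        net.W_pre_str[:] = 0.5
        net.DA = net.p.B_DA
        net.r_pre[:] = 0.5
        net.r_str[:] = 0.4
        before = net.W_pre_str.copy()
        net.plasticity_step()
        assert np.all(net.W_pre_str <= before + 1e-12)

    def test_anticorrelated_pairs_do_not_potentiate(self):
        net = quiet_net()
        net.DA = 1.0  # strong positive phasic signal
        net.r_pre[:] = 0.0
        net.r_pre[0] = 1.0
        net.r_str[:] = 0.0
        net.r_str[3] = 1.0
        net.plasticity_step()
        # pre cell 1 (below mean) onto active striatal cell 3: no growth
        assert net.W_pre_str[1, 3] == 0.0
        # correlated pair did potentiate
        assert net.W_pre_str[0, 3] > 0.0

    def test_weights_stay_non_negative(self):
        net = quiet_net()
        net.DA = 0.0  # strongly negative phasic term
        net.r_pre[:] = 1.0
        net.r_str[:] = 1.0
        for _ in range(50):
            net.plasticity_step()
        assert np.all(net.W_pre_str >= 0.0)
        assert np.all(net.W_str_da >= 0.0)


class TestLibraryGeometry:
    def test_weights_are_normalised_and_frozen_shape(self, rng):
        lib = ActionLibrary(12, 21, rng)
        assert lib.weights.shape == (12, 24, 21)
        assert lib.weights.sum(axis=2) == pytest.approx(np.ones((12, 24)))
        assert np.all(lib.weights >= 0)

    def test_preferred_values_tile_each_interval(self, rng):
        lib = ActionLibrary(3, 21, rng)
        lo, hi = param_grid_bounds()
        assert lib.preferred[:, 0] == pytest.approx(lo)
        assert lib.preferred[:, -1] == pytest.approx(hi)
        diffs = np.diff(lib.preferred, axis=1)
        assert np.all(diffs > 0)
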