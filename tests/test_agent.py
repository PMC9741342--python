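"""Reward shape, epsilon-greedy selection, sample-average updates, episodes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fescycle.agent import (
    ActionValueTable,
    RewardParams,
    StateVector,
    end_episode,
    instantaneous_reward,
    interaction_reward,
    select_action,
    update_estimate,
)
from fescycle.stimulation import (
    ACTIONS,
    NOOP_INDEX,
    Action,
    ChannelConfig,
    ParameterLimits,
    admissible_indices,
)

NOOP = Action(0.0, 0.0)


def reward_at(width_us, amplitude_mA, mean_err=1.0, u=0.0):
    """Reward of a full-circle channel at the given effective parameters."""
    params = RewardParams()
    limits = ParameterLimits()
    ch = ChannelConfig(0, "VM R", amplitude_mA, width_us)
    sv = StateVector(theta_deg=90.0, mean_cadence_error_rpm=mean_err)
    return instantaneous_reward(sv, ch, NOOP, u, params, limits)


class TestInstantaneousReward:
    def test_reference_value_at_default_baseline(self):
        """|0.05^2 * 0.045 - 0.045^2 * (0.1 - 0.045)| / 1 = 1.125e-6."""
        assert reward_at(500.0, 45.0, mean_err=1.0) == pytest.approx(1.125e-6, rel=1e-9)

    def test_zero_outside_window(self):
        ch = ChannelConfig(0, "VM R", 45, 500, theta_start_deg=0.0, theta_end_deg=120.0)
        sv = StateVector(theta_deg=200.0, mean_cadence_error_rpm=1.0)
        assert instantaneous_reward(sv, ch, NOOP, 0.0, RewardParams(), ParameterLimits()) == 0.0

    def test_disabled_channel_gets_no_reward(self):
        ch = ChannelConfig(0, "VM R", 45, 500, enabled=False)
        sv = StateVector(theta_deg=90.0, mean_cadence_error_rpm=1.0)
        assert instantaneous_reward(sv, ch, NOOP, 0.0, RewardParams(), ParameterLimits()) == 0.0

    @pytest.mark.parametrize("amp,increasing", [(75.0, True), (25.0, False)])
    def test_width_preference_flips_with_amplitude(self, amp, increasing):
        """Above the Ma/2 crossing wider pulses earn more, below it less."""
        grid = [450.0, 500.0, 550.0, 600.0]
        rewards = [reward_at(w, amp) for w in grid]
        diffs = np.diff(rewards)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_reward_scales_inversely_with_mean_error(self):
        assert reward_at(500.0, 45.0, mean_err=2.0) == pytest.approx(
            reward_at(500.0, 45.0, mean_err=1.0) / 2.0
        )

    def test_error_floor_clamps_small_errors(self):
        assert reward_at(500.0, 45.0, mean_err=0.0) == reward_at(500.0, 45.0, mean_err=0.1)
        assert np.isfinite(reward_at(500.0, 45.0, mean_err=0.0))


class TestInteractionReward:
    def test_all_samples_gated_out(self):
        assert interaction_reward([], []) == 0.0
        assert interaction_reward([0.0, 0.0], [False, False]) == 0.0

    def test_constant_reward(self):
        assert interaction_reward([2.5] * 10) == pytest.approx(2.5)

    def test_mean_over_active_subset(self):
        rewards = [2.0] * 25 + [0.0] * 25
        active = [True] * 25 + [False] * 25
        assert interaction_reward(rewards, active) == pytest.approx(2.0)


class TestUpdateEstimate:
    def test_first_sample_defines_mean(self):
        t = ActionValueTable()
        update_estimate(t, 0, 2.0)
        assert t.q[0] == 2.0 and t.counts[0] == 1

    def test_running_mean(self):
        t = ActionValueTable()
        for r in (1.0, 2.0, 3.0):
            t.update(4, r)
        assert t.q[4] == pytest.approx(2.0)

    def test_zero_innovation(self):
        t = ActionValueTable()
        t.update(1, 0.7)
        t.update(1, 0.7)
        assert t.q[1] == 0.7

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=60))
    def test_incremental_matches_batch_mean(self, rewards):
        t = ActionValueTable()
        for r in rewards:
            t.update(3, r)
        assert t.q[3] == pytest.approx(float(np.mean(rewards)), abs=1e-12)
        assert t.counts[3] == len(rewards)


class TestSelectAction:
    def test_pure_greedy_is_deterministic(self, rng):
        t = ActionValueTable()
        t.update(7, 1.0)
        for _ in range(50):
            assert select_action(t, 0.0, list(range(9)), rng) == 7

    def test_full_exploration_is_uniform(self, rng):
        """Chi-square over 10^4 draws at epsilon = 1 against the uniform law."""
        from scipy.stats import chisquare

        t = ActionValueTable()
        adm = list(range(9))
        draws = np.array([select_action(t, 1.0, adm, rng) for _ in range(10_000)])
        counts = np.bincount(draws, minlength=9)
        assert chisquare(counts).pvalue > 0.001

    def test_saturation_excludes_width_decreases(self, channel, limits, rng):
        adm = admissible_indices(channel, limits, amplitude_saturated=True)
        excluded = {i for i, a in enumerate(ACTIONS) if a.omega < 0}
        assert not excluded & set(adm)
        t = ActionValueTable()
        for _ in range(200):
            assert select_action(t, 1.0, adm, rng) not in excluded

    def test_empty_admissible_set_is_an_error(self, rng):
        with pytest.raises(ValueError):
            select_action(ActionValueTable(), 0.5, [], rng)

    def test_greedy_after_sampling_every_arm(self, rng):
        """Once every arm has been tried, greedy selection finds the best."""
        t = ActionValueTable()
        for i in range(9):
            t.update(i, 1.0 if i == 2 else 0.5)
        assert select_action(t, 0.0, list(range(9)), rng) == 2


class TestEndEpisode:
    def make(self, n=2):
        limits = ParameterLimits()
        channels = [ChannelConfig(i, "VM R", 45.0, 500.0) for i in range(n)]
        tables = [ActionValueTable() for _ in range(n)]
        return tables, channels, limits

    def test_epsilon_decay_single_step(self, rng):
        tables, channels, limits = self.make()
        _, eps, _ = end_episode(tables, channels, 0.6, 0.99, limits, rng)
        assert eps == pytest.approx(0.594)

    def test_identity_decay(self, rng):
        tables, channels, limits = self.make()
        _, eps, _ = end_episode(tables, channels, 0.4, 1.0, limits, rng)
        assert eps == 0.4

    def test_decay_law_over_many_episodes(self, rng):
        tables, channels, limits = self.make()
        eps = 0.6
        for k in range(1, 41):
            channels, eps, _ = end_episode(tables, channels, eps, 0.99, limits, rng)
            assert eps == pytest.approx(0.6 * 0.99**k, rel=1e-12)

    def test_greedy_action_promoted_into_baseline(self, rng):
        tables, channels, limits = self.make(1)
        idx = ACTIONS.index(Action(1.0, 1.0))
        tables[0].update(idx, 5.0)
        new_channels, _, promoted = end_episode(
            tables, channels, 0.5, 0.99, limits, rng, prefer_noop_on_tie=True
        )
        assert promoted == [idx]
        assert new_channels[0].baseline_amplitude_mA == 45.0 + limits.step_a_mA
        assert new_channels[0].baseline_width_us == 500.0 + limits.step_w_us

    def test_tables_reset_for_independent_episodes(self, rng):
        tables, channels, limits = self.make(1)
        tables[0].update(0, 1.0)
        end_episode(tables, channels, 0.5, 0.99, limits, rng)
        assert tables[0].q == [0.0] * 9
        assert tables[0].counts == [0] * 9

    def test_full_tie_with_noop_preference_keeps_baseline(self, rng):
        tables, channels, limits = self.make(1)
        new_channels, _, promoted = end_episode(
            tables, channels, 0.5, 0.99, limits, rng, prefer_noop_on_tie=True
        )
        assert promoted == [NOOP_INDEX]
        assert new_channels[0] == channels[0]

    def test_full_tie_without_preference_draws_among_admissible(self, rng):
        tables, channels, limits = self.make(1)
        adm = set(admissible_indices(channels[0], limits))
        seen = set()
        for _ in range(200):
            t, ch, lim = self.make(1)
            _, _, promoted = end_episode(t, ch, 0.5, 0.99, lim, rng, prefer_noop_on_tie=False)
            assert promoted[0] in adm
            seen.add(promoted[0])
        assert len(seen) > 1  # the draw really varies over the tie set

    def test_disabled_channel_untouched(self, rng):
        tables, channels, limits = self.make(2)
        channels[1] = dataclasses.replace(channels[1], enabled=False)
        tables[1].update(0, 9.0)
        new_channels, _, _ = end_episode(tables, channels, 0.5, 0.99, limits, rng)
        assert new_channels[1] == channels[1]
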