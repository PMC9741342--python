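"""Decayed-epsilon-greedy adaptation of the stimulation baseline.

The agent treats the nine (amplitude, width) delta actions of each channel as
independent bandit arms.  An action is held for one interaction (5 s by
default) and scored with a reward that trades injected charge against the
moving-average cadence error; action values are estimated by the sample
average of the rewards received within the current episode.  At each episode
boundary (45 s by default) the greedy action of every channel is promoted
into that channel's baseline, the exploration probability is multiplied by
the decay factor, and the value estimates restart from zero, so consecutive
episodes are evaluated independently from the new baseline.

The reward for channel ``c`` at crank angle ``theta`` is

    R = | P_c^2 * A_c  -  Pbar_c^2 * (Ma - A_c) | / e_bar     (theta in window)
    R = 0                                                     (otherwise)

with ``P_c`` the effective pulse width, ``A_c`` the effective amplitude
(baseline + agent delta + PI contribution), ``Pbar_c = Pmax + Pmin - P_c - PK``
a reflected width, all brought to a common scale (1e-4/µs and 1e-3/mA by
default, so 500 µs -> 0.05 and 100 mA -> 0.1), and ``e_bar`` the
moving-average cadence error clamped away from zero.  Below the crossing
amplitude ``Ma/2`` the reward prefers narrow pulses (cheaper stimulation);
above it, wide pulses (more charge headroom before the amplitude ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimulation import (
    ACTIONS,
    NOOP_INDEX,
    Action,
    ChannelConfig,
    ParameterLimits,
    admissible_indices,
    apply_action,
    in_window,
)

__all__ = [
    "StateVector",
    "RewardParams",
    "AgentConfig",
    "ActionValueTable",
    "instantaneous_reward",
    "interaction_reward",
    "select_action",
    "update_estimate",
    "end_episode",
]


@dataclass(frozen=True)
class StateVector:
    """Observed state: crank angle (deg) and moving-average cadence error (rpm)."""

    theta_deg: float
    mean_cadence_error_rpm: float


@dataclass(frozen=True)
class RewardParams:
    """Constants of the charge-vs-error reward.

    ``pk_us`` is the reward offset expressed in width units (µs) before
    scaling; with the defaults the reflected width ``Pbar`` spans
    [350, 500] µs over the admissible width range.  ``error_floor_rpm``
    clamps the moving-average cadence error away from zero so the reward
    stays finite during perfect tracking.
    """

    ma_mA: float = 100.0
    pk_us: float = 100.0
    p_max_us: float = 600.0
    p_min_us: float = 450.0
    amplitude_scale: float = 1e-3  # per mA
    width_scale: float = 1e-4  # per µs
    error_floor_rpm: float = 0.1


@dataclass(frozen=True)
class AgentConfig:
    """Exploration schedule, interaction clocks and reward constants."""

    epsilon0: float = 0.6
    decay_rate: float = 0.99
    interaction_period_s: float = 5.0
    episode_length_s: float = 45.0
    reward: RewardParams = field(default_factory=RewardParams)
    prefer_noop_on_tie: bool = True
    error_window: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon0 <= 1.0):
            raise ValueError("epsilon0 must lie in [0, 1]")
        if not (0.0 <= self.decay_rate <= 1.0):
            raise ValueError("decay_rate must lie in [0, 1]")
        ratio = self.episode_length_s / self.interaction_period_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "episode_length_s must be an integer multiple of interaction_period_s"
            )

    @property
    def interactions_per_episode(self) -> int:
        return round(self.episode_length_s / self.interaction_period_s)


def instantaneous_reward(
    state: StateVector,
    channel: ChannelConfig,
    action: Action,
    u_mA: float,
    params: RewardParams,
    limits: ParameterLimits,
) -> float:
    """Per-sample reward for one channel; exactly 0 outside its angle window.

    The effective amplitude ``baseline + alpha*k_a + u`` is clipped to
    [0, Ma] (the stimulator ceiling) and the effective width to
    [w_min, w_max] before scaling.
    """
    if not channel.enabled or not in_window(state.theta_deg, channel):
        return 0.0
    w_eff = channel.baseline_width_us + action.omega * limits.step_w_us
    w_eff = min(max(w_eff, limits.w_min_us), limits.w_max_us)
    a_eff = channel.baseline_amplitude_mA + action.alpha * limits.step_a_mA + u_mA
    a_eff = min(max(a_eff, 0.0), params.ma_mA)
    p = w_eff * params.width_scale
    a = a_eff * params.amplitude_scale
    ma = params.ma_mA * params.amplitude_scale
    pbar = (params.p_max_us + params.p_min_us - w_eff - params.pk_us) * params.width_scale
    e_bar = max(abs(state.mean_cadence_error_rpm), params.error_floor_rpm)
    return abs(p * p * a - pbar * pbar * (ma - a)) / e_bar


def interaction_reward(
    rewards: Sequence[float],
    active: Sequence[bool] | None = None,
) -> float:
    """Pool the per-sample rewards of one interaction window into one scalar.

    Returns the mean of the in-window (non-gated) samples; if the crank never
    entered the channel's window during the interaction, the reward is 0.
    ``active`` marks which samples were inside the window; when omitted, all
    samples are treated as active.
    """
    if active is None:
        vals = list(rewards)
    else:
        vals = [r for r, a in zip(rewards, active) if a]
    if not vals:
        return 0.0
    return float(sum(vals) / len(vals))


class ActionValueTable:
    """Sample-average action values and selection counts for one channel.

    ``q[i]`` is the incremental running mean of the rewards received for
    action ``i`` within the current episode; ``counts[i]`` the number of
    times the action was selected.  Both reset at episode boundaries.
    """

    def __init__(self, n_actions: int = len(ACTIONS)) -> None:
        self.n_actions = n_actions
        self.q = [0.0] * n_actions
        self.counts = [0] * n_actions

    def reset(self) -> None:
        for i in range(self.n_actions):
            self.q[i] = 0.0
            self.counts[i] = 0

    def update(self, index: int, reward: float) -> None:
        """NewEstimate <- OldEstimate + (Reward - OldEstimate)/n."""
        if not (0 <= index < self.n_actions):
            raise IndexError(f"action index {index} out of range")
        self.counts[index] += 1
        self.q[index] += (reward - self.q[index]) / self.counts[index]

    def greedy(
        self,
        admissible: Sequence[int],
        rng: np.random.Generator,
        prefer_noop_on_tie: bool = False,
        noop_index: int = NOOP_INDEX,
    ) -> int:
        """Admissible action with the greatest value; seeded uniform tie-break.

        With ``prefer_noop_on_tie``, a full tie across the admissible set
        (e.g. an episode without any in-window reward) resolves to the
        identity action so the baseline does not drift while unrewarded.
        """
        if not admissible:
            raise ValueError("admissible action set must not be empty")
        best = max(self.q[i] for i in admissible)
        maxima = [i for i in admissible if self.q[i] == best]
        if prefer_noop_on_tie and len(maxima) == len(admissible) and noop_index in maxima:
            return noop_index
        if len(maxima) == 1:
            return maxima[0]
        return maxima[int(rng.integers(len(maxima)))]


def update_estimate(table: ActionValueTable, index: int, reward: float) -> ActionValueTable:
    """Incremental sample-average update; returns the (mutated) table."""
    table.update(index, reward)
    return table


def select_action(
    table: ActionValueTable,
    epsilon: float,
    admissible: Sequence[int],
    rng: np.random.Generator,
    prefer_noop_on_tie: bool = False,
) -> int:
    """Epsilon-greedy selection over the admissible action subset.

    With probability ``epsilon`` a uniform draw over the admissible actions
    (exploration); otherwise the greedy admissible action, ties broken by a
    seeded uniform draw among the maxima.
    """
    if not admissible:
        raise ValueError("admissible action set must not be empty")
    if rng.random() < epsilon:
        return admissible[int(rng.integers(len(admissible)))]
    return table.greedy(admissible, rng, prefer_noop_on_tie=prefer_noop_on_tie)


def end_episode(
    tables: Sequence[ActionValueTable],
    channels: Sequence[ChannelConfig],
    epsilon: float,
    decay_rate: float,
    limits: ParameterLimits,
    rng: np.random.Generator,
    amplitude_saturated: Sequence[bool] | None = None,
    reference_amplitudes_mA: Sequence[float] | None = None,
    prefer_noop_on_tie: bool = True,
) -> tuple[list[ChannelConfig], float, list[int]]:
    """Promote each channel's greedy action into its baseline and decay epsilon.

    Returns the updated channels, ``epsilon * decay_rate`` and the promoted
    action indices.  Value tables are reset so the next episode restarts its
    estimates from the new baseline, independent of the previous one.
    """
    if len(tables) != len(channels):
        raise ValueError("one value table per channel required")
    sat = amplitude_saturated or [False] * len(channels)
    refs = reference_amplitudes_mA or [None] * len(channels)
    new_channels: list[ChannelConfig] = []
    promoted: list[int] = []
    for table, channel, saturated, ref in zip(tables, channels, sat, refs):
        if not channel.enabled:
            new_channels.append(channel)
            promoted.append(NOOP_INDEX)
            table.reset()
            continue
        adm = admissible_indices(channel, limits, saturated, ref)
        idx = table.greedy(adm, rng, prefer_noop_on_tie=prefer_noop_on_tie)
        new_channels.append(
            apply_action(channel, ACTIONS[idx], limits, saturated, ref)
        )
        promoted.append(idx)
        table.reset()
    return new_channels, epsilon * decay_rate, promoted
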