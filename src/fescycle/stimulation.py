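"""Stimulation-channel primitives: pulse parameters, the agent's action algebra,
angular gating and injected-charge accounting.

A stimulation channel is one electrode pair over a muscle group (VM, VL+RF or
HAM, left or right leg).  Each channel carries a baseline pulse amplitude (mA),
pulse width (µs) and frequency (Hz), and is only active while the crank angle
lies inside its angular window.  The adaptation agent perturbs the amplitude
and width baselines by multiples of fixed step sizes, the multipliers being
drawn from the three-element set ``D3 = {-0.5, 0, 1}``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "D3",
    "Action",
    "ACTIONS",
    "NOOP_INDEX",
    "ChannelConfig",
    "ParameterLimits",
    "StimulationCommand",
    "InadmissibleActionError",
    "enumerate_actions",
    "action_index",
    "apply_action",
    "is_admissible",
    "admissible_indices",
    "pulse_charge_rate",
    "in_window",
]

#: Multiplier set for amplitude/width deltas, in the fixed enumeration order.
D3: tuple[float, ...] = (-0.5, 0.0, 1.0)


class InadmissibleActionError(ValueError):
    """Raised when an action violates the selection rules for a channel.

    Callers holding an exploration policy are expected to catch this (or to
    pre-filter with :func:`is_admissible`) and resample another action.
    """


@dataclass(frozen=True)
class Action:
    """One (alpha, omega) delta pair; both components must come from ``D3``.

    ``alpha`` multiplies the amplitude step (mA), ``omega`` the width step (µs).
    """

    alpha: float
    omega: float

    def __post_init__(self) -> None:
        if self.alpha not in D3 or self.omega not in D3:
            raise ValueError(
                f"action components must be drawn from D3={D3}, "
                f"got ({self.alpha}, {self.omega})"
            )

    @property
    def is_noop(self) -> bool:
        return self.alpha == 0.0 and self.omega == 0.0


def enumerate_actions(n_params: int) -> list[tuple[float, ...]]:
    """Enumerate all ``|D3|**n_params`` delta tuples in lexicographic order.

    The order is lexicographic over the parameter multipliers with ``D3``
    ordered ``(-0.5, 0, 1)``; index 0 is ``(-0.5, ..., -0.5)`` and the last
    index is ``(1, ..., 1)``.  The ordering is stable across runs and is the
    index map used by the action-value tables.
    """
    if n_params < 1:
        raise ValueError(f"n_params must be >= 1, got {n_params}")
    return list(itertools.product(D3, repeat=n_params))


#: The default two-parameter action set (amplitude, width): nine actions.
ACTIONS: tuple[Action, ...] = tuple(Action(a, w) for a, w in enumerate_actions(2))

#: Index of the identity action (0, 0) in :data:`ACTIONS`.
NOOP_INDEX: int = ACTIONS.index(Action(0.0, 0.0))


def action_index(action: Action) -> int:
    """Index of ``action`` in the canonical nine-element set."""
    return ACTIONS.index(action)


@dataclass(frozen=True)
class ParameterLimits:
    """Hard limits and step sizes for the pulse parameters.

    ``delta_a_mA`` bounds the agent-controlled amplitude baseline to an
    excursion around the session's initial baseline (a0 ± delta_a), further
    clipped to [0, ma_mA].  The width is governed by the asymmetric hard
    bounds [w_min_us, w_max_us]; ``delta_w_us`` is informational.
    """

    ma_mA: float = 100.0
    w_min_us: float = 450.0
    w_max_us: float = 600.0
    delta_a_mA: float = 10.0
    delta_w_us: float = 100.0
    step_a_mA: float = 2.0
    step_w_us: float = 20.0

    def __post_init__(self) -> None:
        if not self.w_min_us < self.w_max_us:
            raise ValueError("w_min_us must be < w_max_us")
        if self.step_a_mA <= 0 or self.step_w_us <= 0:
            raise ValueError("step sizes must be positive")
        if self.delta_a_mA < 0 or self.delta_w_us < 0:
            raise ValueError("parameter excursions must be >= 0")


@dataclass(frozen=True)
class ChannelConfig:
    """One stimulation channel's baseline parameters and angular window.

    Angles are degrees in [0, 360]; a window with ``theta_start_deg >
    theta_end_deg`` wraps through 0°, and ``(0, 360)`` (or equal endpoints)
    denotes the full circle.
    """

    channel_id: int
    muscle_label: str
    baseline_amplitude_mA: float
    baseline_width_us: float
    frequency_hz: float = 35.0
    theta_start_deg: float = 0.0
    theta_end_deg: float = 360.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.baseline_amplitude_mA < 0:
            raise ValueError("baseline amplitude must be >= 0 mA")
        if self.baseline_width_us <= 0:
            raise ValueError("baseline width must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        for name in ("theta_start_deg", "theta_end_deg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 360.0):
                raise ValueError(f"{name} must lie in [0, 360], got {v}")


@dataclass(frozen=True)
class StimulationCommand:
    """Effective per-tick output of the general controller for one channel."""

    channel_id: int
    amplitude_mA: float
    width_us: float
    frequency_hz: float
    active: bool


def in_window(theta_deg: float, channel: ChannelConfig) -> bool:
    """True iff the crank angle lies inside the channel's stimulation window.

    The window is closed at both ends.  Windows wrapping through 0°/360°
    (start > end) are supported; equal endpoints or (0, 360) mean the full
    circle.
    """
    start, end = channel.theta_start_deg, channel.theta_end_deg
    if start == end or (start == 0.0 and end == 360.0):
        return True
    theta = theta_deg % 360.0
    start %= 360.0
    end %= 360.0
    if start <= end:
        return start <= theta <= end
    return theta >= start or theta <= end


def is_admissible(
    channel: ChannelConfig,
    action: Action,
    limits: ParameterLimits,
    amplitude_saturated: bool = False,
    reference_amplitude_mA: float | None = None,
) -> bool:
    """Check the two action-selection rules for one channel.

    Rule 1: the resulting amplitude baseline must stay inside
    ``[a0 - delta_a, a0 + delta_a] ∩ [0, Ma]`` (``a0`` is
    ``reference_amplitude_mA``, by default the channel's current baseline)
    and the resulting width inside ``[w_min, w_max]``.

    Rule 2: while the effective amplitude is pinned at its maximum, the
    width may not be decreased (increasing it remains allowed).
    """
    if amplitude_saturated and action.omega < 0:
        return False
    a0 = (
        channel.baseline_amplitude_mA
        if reference_amplitude_mA is None
        else reference_amplitude_mA
    )
    a_new = channel.baseline_amplitude_mA + action.alpha * limits.step_a_mA
    lo = max(0.0, a0 - limits.delta_a_mA)
    hi = min(limits.ma_mA, a0 + limits.delta_a_mA)
    if not (lo - 1e-9 <= a_new <= hi + 1e-9):
        return False
    w_new = channel.baseline_width_us + action.omega * limits.step_w_us
    if not (limits.w_min_us - 1e-9 <= w_new <= limits.w_max_us + 1e-9):
        return False
    return True


def admissible_indices(
    channel: ChannelConfig,
    limits: ParameterLimits,
    amplitude_saturated: bool = False,
    reference_amplitude_mA: float | None = None,
    actions: Sequence[Action] = ACTIONS,
) -> list[int]:
    """Indices of the admissible subset of ``actions`` for this channel.

    Never empty: the identity action (0, 0) is always admissible.
    """
    return [
        i
        for i, a in enumerate(actions)
        if is_admissible(channel, a, limits, amplitude_saturated, reference_amplitude_mA)
    ]


def apply_action(
    channel: ChannelConfig,
    action: Action,
    limits: ParameterLimits,
    amplitude_saturated: bool = False,
    reference_amplitude_mA: float | None = None,
) -> ChannelConfig:
    """Return a new channel with ``a' = a + alpha*k_a`` and ``w' = w + omega*k_w``.

    Frequency and the angular window are untouched; the input channel is not
    modified.  Raises :class:`InadmissibleActionError` if the action violates
    the selection rules, in which case the caller must choose another one.
    """
    if not is_admissible(channel, action, limits, amplitude_saturated, reference_amplitude_mA):
        raise InadmissibleActionError(
            f"action ({action.alpha}, {action.omega}) is not admissible for "
            f"channel {channel.channel_id} at a={channel.baseline_amplitude_mA} mA, "
            f"w={channel.baseline_width_us} µs"
        )
    return replace(
        channel,
        baseline_amplitude_mA=channel.baseline_amplitude_mA + action.alpha * limits.step_a_mA,
        baseline_width_us=channel.baseline_width_us + action.omega * limits.step_w_us,
    )


def pulse_charge_rate(
    amplitude_mA: float,
    width_us: float,
    frequency_hz: float,
    both_phases: bool = False,
) -> float:
    """Injected charge rate in µC/s for a rectangular pulse train.

    Charge per phase is amplitude (mA) × width (µs) = nC, i.e. 1e-3 µC; the
    rate is charge per pulse times the pulse frequency.  By default only the
    leading phase of the symmetric biphasic pulse is counted ("injected
    charge"); set ``both_phases=True`` to count the charge-balanced second
    phase as well.
    """
    if amplitude_mA < 0 or width_us < 0 or frequency_hz < 0:
        raise ValueError("amplitude, width and frequency must all be >= 0")
    per_pulse_uC = amplitude_mA * width_us * 1e-3
    if both_phases:
        per_pulse_uC *= 2.0
    return per_pulse_uC * frequency_hz
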