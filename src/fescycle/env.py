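"""Synthetic rider + tricycle stand-in for desk-scale closed-loop testing.

The plant is deliberately simple — it exists to exercise the controller, not
to be a validated musculoskeletal model.  It combines:

* a first-order crank: ``J dω/dt = τ_muscle − b ω − τ_load``, with the load
  torque opposing motion only (the crank cannot be driven backwards; cadence
  is floored at zero),
* per-channel angle-gated torque generation: each stimulated muscle group
  contributes a raised-cosine torque bump ``g_c(θ)`` over its stimulation
  window, scaled by its activation,
* a piecewise-linear recruitment curve mapping pulse charge rate (µC/s) to
  activation in [0, 1] between a threshold and a saturation level,
* a scalar fatigue state ``φ_c`` per channel in ``[φ_min, 1]`` that decays
  under activation and recovers at rest:
  ``dφ/dt = −λ·act·(φ − φ_min) + ρ·(1 − act)·(1 − φ)``,
* an incremental-encoder measurement model: the crank angle is quantized to
  the encoder resolution and the cadence derived from count differences over
  the 10-Hz reporting window, which makes the cadence signal discrete.

Two named presets, M1 and M2, mirror the two tricycle gear ratios; M2 is the
heavier one (larger load torque and inertia, longer distance per crank
revolution).  The constants were calibrated once so that a PI-only session
at default gains saturates the amplitude within 20–40 simulated minutes on
M2, later on M1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

from .stimulation import ChannelConfig, StimulationCommand, pulse_charge_rate

__all__ = [
    "MuscleProfile",
    "Recruitment",
    "FatigueParams",
    "EnvConfig",
    "EnvState",
    "Measurement",
    "env_step",
    "measure",
    "initial_state",
    "env_preset",
    "default_channels",
    "DEFAULT_PROFILES",
]

RPM_TO_RAD_S = 2.0 * math.pi / 60.0
RAD_S_TO_RPM = 60.0 / (2.0 * math.pi)


@dataclass(frozen=True)
class MuscleProfile:
    """Raised-cosine torque-angle bump for one channel at full activation.

    ``g(θ) = peak · ½(1 + cos(2π Δ / width))`` for circular distance
    ``|Δ| ≤ width/2`` from the center, zero elsewhere.  A width ≥ 360° means
    a flat profile of height ``peak`` over the whole circle (useful for
    analytic closed-form checks).
    """

    center_deg: float
    width_deg: float
    peak_torque_nm: float

    def torque_gain(self, theta_deg: float) -> float:
        if self.width_deg >= 360.0:
            return self.peak_torque_nm
        d = (theta_deg - self.center_deg) % 360.0
        if d > 180.0:
            d -= 360.0
        half = 0.5 * self.width_deg
        if abs(d) > half:
            return 0.0
        return self.peak_torque_nm * 0.5 * (1.0 + math.cos(math.pi * d / half))

    @property
    def support(self) -> tuple[float, float]:
        """(start, end) angles of the nonzero support, wrapped to [0, 360)."""
        if self.width_deg >= 360.0:
            return (0.0, 360.0)
        start = (self.center_deg - 0.5 * self.width_deg) % 360.0
        end = (self.center_deg + 0.5 * self.width_deg) % 360.0
        return (start, end)


@dataclass(frozen=True)
class Recruitment:
    """Piecewise-linear charge-rate → activation map with threshold and saturation."""

    threshold_uC_s: float = 200.0
    saturation_uC_s: float = 2500.0

    def activation(self, charge_rate_uC_s: float) -> float:
        span = self.saturation_uC_s - self.threshold_uC_s
        a = (charge_rate_uC_s - self.threshold_uC_s) / span
        return min(max(a, 0.0), 1.0)


@dataclass(frozen=True)
class FatigueParams:
    """First-order fatigue/recovery dynamics of the muscle fitness scalar."""

    rate_per_s: float = 0.0006  # λ: fitness loss per unit activation·s
    recovery_per_s: float = 1e-4  # ρ: recovery toward 1 at rest
    floor: float = 0.25  # φ_min: residual fitness
    enabled: bool = True
    initial: float = 1.0


@dataclass(frozen=True)
class EnvConfig:
    """All plant constants; two named presets are provided by :func:`env_preset`."""

    name: str = "custom"
    inertia_kgm2: float = 8.0
    damping_nms_rad: float = 0.5
    load_torque_nm: float = 3.0
    meters_per_rev: float = 2.05
    profiles: tuple[MuscleProfile, ...] = ()
    recruitment: Recruitment = field(default_factory=Recruitment)
    fatigue: FatigueParams = field(default_factory=FatigueParams)
    dt_internal_s: float = 0.01
    encoder_counts_per_rev: int = 1440
    torque_noise_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.inertia_kgm2 <= 0 or self.damping_nms_rad <= 0:
            raise ValueError("inertia and damping must be positive")
        if self.dt_internal_s <= 0:
            raise ValueError("dt_internal_s must be positive")


@dataclass
class EnvState:
    """Crank kinematics, per-channel fitness and elapsed time."""

    theta_deg: float = 0.0
    cadence_rpm: float = 0.0
    fitness: list[float] = field(default_factory=list)
    time_s: float = 0.0
    theta_unwrapped_deg: float = 0.0
    power_w: float = 0.0  # instantaneous crank power from muscle torque


class Measurement(NamedTuple):
    theta_deg: float
    cadence_rpm: float
    count: int


def initial_state(config: EnvConfig, cadence_rpm: float = 0.0, theta_deg: float = 0.0) -> EnvState:
    n = len(config.profiles)
    return EnvState(
        theta_deg=theta_deg % 360.0,
        cadence_rpm=cadence_rpm,
        fitness=[config.fatigue.initial] * n,
        time_s=0.0,
        theta_unwrapped_deg=theta_deg,
    )


def env_step(
    state: EnvState,
    commands: Sequence[StimulationCommand],
    config: EnvConfig,
    dt_s: float,
    rng=None,
) -> EnvState:
    """Advance the plant by ``dt_s`` under the given stimulation commands.

    Semi-implicit Euler with internal sub-stepping whenever ``dt_s`` exceeds
    the internal step (10 ms by default).  Commands are held constant over
    the step; the angular gating of torque and fatigue follows the true
    crank angle through each sub-step via the torque-profile support.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    n_sub = max(1, math.ceil(dt_s / config.dt_internal_s - 1e-9))
    h = dt_s / n_sub

    profiles = config.profiles
    n_ch = len(profiles)
    # commanded activation level per channel (before fatigue and gating)
    act_cmd = [0.0] * n_ch
    for cmd in commands:
        if 0 <= cmd.channel_id < n_ch and cmd.active:
            q = pulse_charge_rate(cmd.amplitude_mA, cmd.width_us, cmd.frequency_hz)
            act_cmd[cmd.channel_id] = config.recruitment.activation(q)

    theta = state.theta_deg
    theta_unwrapped = state.theta_unwrapped_deg
    omega = state.cadence_rpm * RPM_TO_RAD_S
    fitness = list(state.fitness) if state.fitness else [config.fatigue.initial] * n_ch
    b = config.damping_nms_rad
    j = config.inertia_kgm2
    tau_load = config.load_torque_nm
    fat = config.fatigue
    noise = config.torque_noise_rel
    power = state.power_w

    for _ in range(n_sub):
        tau_m = 0.0
        for c in range(n_ch):
            a_cmd = act_cmd[c]
            g = profiles[c].torque_gain(theta)
            drive = a_cmd if g > 0.0 else 0.0
            if drive > 0.0:
                tau_m += drive * fitness[c] * g
            if fat.enabled:
                phi = fitness[c]
                dphi = (
                    -fat.rate_per_s * drive * (phi - fat.floor)
                    + fat.recovery_per_s * (1.0 - drive) * (1.0 - phi)
                )
                phi += dphi * h
                fitness[c] = min(max(phi, fat.floor), 1.0)
        if noise > 0.0 and rng is not None and tau_m > 0.0:
            tau_m *= 1.0 + noise * float(rng.standard_normal())
        power = tau_m * omega
        if omega > 0.0:
            tau_net = tau_m - b * omega - tau_load
        else:
            # static friction: the load torque only resists, never drives
            tau_net = tau_m - tau_load
            if tau_net < 0.0:
                tau_net = 0.0
        omega += tau_net / j * h
        if omega < 0.0:
            omega = 0.0
        d_theta = omega * h * (180.0 / math.pi)
        theta_unwrapped += d_theta
        theta = (theta + d_theta) % 360.0

    if not (math.isfinite(theta) and math.isfinite(omega)):
        raise FloatingPointError(
            f"environment state diverged at t={state.time_s + dt_s:.2f} s: "
            f"theta={theta}, omega={omega}"
        )
    return EnvState(
        theta_deg=theta,
        cadence_rpm=omega * RAD_S_TO_RPM,
        fitness=fitness,
        time_s=state.time_s + dt_s,
        theta_unwrapped_deg=theta_unwrapped,
        power_w=power,
    )


def encoder_count(state: EnvState, counts_per_rev: int) -> int:
    """Cumulative encoder count for the unwrapped crank angle."""
    return math.floor(state.theta_unwrapped_deg / 360.0 * counts_per_rev)


def measure(
    state: EnvState,
    counts_per_rev: int,
    prev_count: int | None = None,
    dt_s: float = 0.1,
) -> Measurement:
    """Encoder-like observation of crank angle and cadence.

    The angle is floor-quantized to the encoder resolution.  The cadence is
    computed from the count difference over the reporting window ``dt_s``
    (0 when no previous count is available), so it is inherently discrete —
    one count per window corresponds to ``60 / (counts_per_rev · dt_s)`` rpm.
    """
    count = encoder_count(state, counts_per_rev)
    step = 360.0 / counts_per_rev
    theta_q = (count % counts_per_rev) * step
    if prev_count is None:
        cadence = 0.0
    else:
        cadence = (count - prev_count) / counts_per_rev / dt_s * 60.0
    return Measurement(theta_deg=theta_q, cadence_rpm=cadence, count=count)


# ---------------------------------------------------------------------------
# Default muscle layout and gear presets
# ---------------------------------------------------------------------------

#: Torque-angle bumps per channel (0–2 right leg, 3–5 left leg, 180° apart).
#: Channel order: VM, VL+RF, HAM for each leg.  The stimulation windows of
#: :func:`default_channels` coincide with the bump supports.
DEFAULT_PROFILES: tuple[MuscleProfile, ...] = (
    MuscleProfile(center_deg=80.0, width_deg=120.0, peak_torque_nm=13.0),  # VM R
    MuscleProfile(center_deg=20.0, width_deg=120.0, peak_torque_nm=13.0),  # VL+RF R
    MuscleProfile(center_deg=140.0, width_deg=120.0, peak_torque_nm=9.0),  # HAM R
    MuscleProfile(center_deg=260.0, width_deg=120.0, peak_torque_nm=13.0),  # VM L
    MuscleProfile(center_deg=200.0, width_deg=120.0, peak_torque_nm=13.0),  # VL+RF L
    MuscleProfile(center_deg=320.0, width_deg=120.0, peak_torque_nm=9.0),  # HAM L
)

_MUSCLE_LABELS = ("VM R", "VL+RF R", "HAM R", "VM L", "VL+RF L", "HAM L")


def env_preset(name: str) -> EnvConfig:
    """Named gear-ratio presets: ``m1`` (lighter) and ``m2`` (heavier)."""
    key = name.lower()
    base = EnvConfig(
        name="m1",
        inertia_kgm2=8.0,
        damping_nms_rad=0.5,
        load_torque_nm=3.0,
        meters_per_rev=2.05,
        profiles=DEFAULT_PROFILES,
    )
    if key == "m1":
        return base
    if key == "m2":
        return replace(
            base,
            name="m2",
            inertia_kgm2=10.0,
            load_torque_nm=5.0,
            meters_per_rev=2.30,
        )
    raise ValueError(f"unknown environment preset {name!r} (expected 'm1' or 'm2')")


def default_channels(
    right_amplitude_mA: float = 45.0,
    left_amplitude_mA: float = 50.0,
    width_us: float = 500.0,
    frequency_hz: float = 35.0,
    profiles: Sequence[MuscleProfile] = DEFAULT_PROFILES,
) -> tuple[ChannelConfig, ...]:
    """Six-channel layout with windows matching the default torque profiles.

    Channels 0–2 stimulate the right leg (45 mA default baseline), 3–5 the
    left leg (50 mA), all at 500 µs / 35 Hz.
    """
    channels = []
    for cid, (profile, label) in enumerate(zip(profiles, _MUSCLE_LABELS)):
        start, end = profile.support
        amp = right_amplitude_mA if cid < 3 else left_amplitude_mA
        channels.append(
            ChannelConfig(
                channel_id=cid,
                muscle_label=label,
                baseline_amplitude_mA=amp,
                baseline_width_us=width_us,
                frequency_hz=frequency_hz,
                theta_start_deg=start,
                theta_end_deg=end,
            )
        )
    return tuple(channels)
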