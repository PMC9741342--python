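"""Full closed-loop session orchestration and 10-Hz logging.

A session runs the control loop at the control rate (10 Hz by default):
measure the crank through the encoder model, advance the PI cadence
controller, do the agent's interaction/episode bookkeeping (a new action
every 5 s, a baseline promotion and epsilon decay every 45 s), build the
per-channel stimulation commands, step the synthetic environment and append
one log record.  Sessions are fully reproducible under a fixed seed.

The log mirrors the fields the stimulation app records: per tick the
reference and measured cadence, crank angle, per-channel on/off state and
effective pulse parameters, the agent's action index and reward, the PI
output, epsilon and the episode index, plus synthetic-only diagnostics
(true cadence, muscle fitness, crank power).  Logs are saved as CSV with a
JSON header block carrying the fully resolved configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import pi as pi_mod
from .agent import (
    ActionValueTable,
    AgentConfig,
    RewardParams,
    StateVector,
    end_episode,
    instantaneous_reward,
    interaction_reward,
    select_action,
)
from .env import (
    EnvConfig,
    default_channels,
    encoder_count,
    env_preset,
    env_step,
    initial_state,
    measure,
)
from .pi import PIState, pi_step
from .stimulation import (
    ACTIONS,
    NOOP_INDEX,
    ChannelConfig,
    ParameterLimits,
    StimulationCommand,
    in_window,
    is_admissible,
)

__all__ = [
    "SessionConfig",
    "SessionLog",
    "run_session",
    "scenario_presets",
    "session_config_from_dict",
    "load_session_config",
    "N_CHANNELS",
]

N_CHANNELS = 6

SCENARIOS = ("pi_only", "pi_rl")


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to reproduce one session."""

    scenario: str = "pi_rl"
    env: EnvConfig = field(default_factory=lambda: env_preset("m1"))
    agent: AgentConfig = field(default_factory=AgentConfig)
    limits: ParameterLimits = field(default_factory=ParameterLimits)
    channels: tuple[ChannelConfig, ...] | None = None
    reference_rpm: float = 35.0
    duration_s: float = 3600.0
    control_rate_hz: float = 10.0
    seed: int = 0
    initial_cadence_rpm: float = 15.0
    kp: float = pi_mod.DEFAULT_KP
    ki: float = pi_mod.DEFAULT_KI
    anti_windup: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.control_rate_hz <= 0:
            raise ValueError("control_rate_hz must be positive")
        if self.channels is not None:
            _validate(self.channels, self.limits)

    def resolved_channels(self) -> tuple[ChannelConfig, ...]:
        if self.channels is not None:
            return self.channels
        return default_channels(profiles=self.env.profiles)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = [dataclasses.asdict(c) for c in self.resolved_channels()]
        return d


@dataclass
class SessionLog:
    """Header (resolved config, seed, online totals) plus the 10-Hz record stream."""

    header: dict
    data: pd.DataFrame

    def save(self, path) -> None:
        """CSV with '#'-prefixed JSON header lines, then the column block."""
        header_json = json.dumps(self.header, sort_keys=True, default=float)
        with open(path, "w", newline="") as fh:
            fh.write(f"# {header_json}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "SessionLog":
        header: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                header = json.loads(line[1:].strip())
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            data = pd.read_csv(fh)
        return cls(header=header, data=data)


def channel_columns(i: int) -> list[str]:
    return [
        f"ch{i}_on",
        f"ch{i}_amplitude_mA",
        f"ch{i}_width_us",
        f"ch{i}_frequency_hz",
        f"ch{i}_action",
        f"ch{i}_reward",
        f"ch{i}_fitness",
    ]


BASE_COLUMNS = [
    "t_s",
    "episode",
    "epsilon",
    "theta_deg",
    "cadence_rpm",
    "cadence_true_rpm",
    "reference_rpm",
    "cadence_error_rpm",
    "mean_error_rpm",
    "pi_u_mA",
    "power_w",
]


def run_session(config: SessionConfig) -> SessionLog:
    """Run one full session and return its log.

    The interaction and episode clocks are tick-based (50 and 450 ticks at
    10 Hz), and the first action of each episode is selected immediately at
    the episode boundary after the baseline promotion.
    """
    channels = list(config.resolved_channels())
    limits = config.limits
    agent_cfg = config.agent
    use_agent = config.scenario == "pi_rl"
    _validate(channels, limits)

    dt = 1.0 / config.control_rate_hz
    n_ticks = round(config.duration_s * config.control_rate_hz)
    ticks_per_interaction = max(1, round(agent_cfg.interaction_period_s * config.control_rate_hz))
    ticks_per_episode = max(1, round(agent_cfg.episode_length_s * config.control_rate_hz))

    ss = np.random.SeedSequence(config.seed)
    rng_agent, rng_env = (np.random.default_rng(s) for s in ss.spawn(2))

    env_cfg = config.env
    state = initial_state(env_cfg, cadence_rpm=config.initial_cadence_rpm)
    # back-fill the previous encoder count assuming constant initial cadence
    prev_count = encoder_count(
        replace_unwrapped(state, state.theta_unwrapped_deg - config.initial_cadence_rpm * 6.0 * dt),
        env_cfg.encoder_counts_per_rev,
    )

    pi_state = PIState(kp=config.kp, ki=config.ki, anti_windup=config.anti_windup)
    reward_params: RewardParams = agent_cfg.reward
    ma = limits.ma_mA

    initial_amps = [c.baseline_amplitude_mA for c in channels]
    tables = [ActionValueTable(len(ACTIONS)) for _ in channels]
    current_actions = [None] * len(channels)  # type: list[int | None]
    inter_sum = [0.0] * len(channels)
    inter_cnt = [0] * len(channels)
    epsilon = agent_cfg.epsilon0
    episode = 0

    err_window: deque[float] = deque(maxlen=agent_cfg.error_window)
    rows = []
    total_reward = 0.0
    total_abs_error = 0.0
    distance_m = 0.0

    for tick in range(n_ticks):
        t = tick * dt
        meas = measure(state, env_cfg.encoder_counts_per_rev, prev_count, dt)
        prev_count = meas.count
        err = config.reference_rpm - meas.cadence_rpm
        err_window.append(err)
        mean_err = sum(err_window) / len(err_window)

        def agent_alpha(i: int) -> float:
            idx = current_actions[i]
            return ACTIONS[idx].alpha if idx is not None else 0.0

        def agent_omega(i: int) -> float:
            idx = current_actions[i]
            return ACTIONS[idx].omega if idx is not None else 0.0

        agent_amps = [
            channels[i].baseline_amplitude_mA + agent_alpha(i) * limits.step_a_mA
            for i in range(len(channels))
            if channels[i].enabled
        ]
        u_max = ma - max(agent_amps) if agent_amps else ma
        pi_state = dataclasses.replace(pi_state, u_max_mA=max(u_max, 0.0))
        pi_state, u = pi_step(pi_state, config.reference_rpm, meas.cadence_rpm, dt)

        saturated = [
            channels[i].enabled
            and channels[i].baseline_amplitude_mA + agent_alpha(i) * limits.step_a_mA + u
            >= ma - 1e-9
            for i in range(len(channels))
        ]

        if use_agent:
            boundary = tick % ticks_per_interaction == 0
            if boundary and tick > 0:
                for i, table in enumerate(tables):
                    if current_actions[i] is None or not channels[i].enabled:
                        continue
                    r = inter_sum[i] / inter_cnt[i] if inter_cnt[i] else 0.0
                    table.update(current_actions[i], r)
                    inter_sum[i] = 0.0
                    inter_cnt[i] = 0
                if tick % ticks_per_episode == 0:
                    channels, epsilon, _ = end_episode(
                        tables,
                        channels,
                        epsilon,
                        agent_cfg.decay_rate,
                        limits,
                        rng_agent,
                        amplitude_saturated=saturated,
                        reference_amplitudes_mA=initial_amps,
                        prefer_noop_on_tie=agent_cfg.prefer_noop_on_tie,
                    )
                    episode += 1
            if boundary:
                for i, table in enumerate(tables):
                    if not channels[i].enabled:
                        current_actions[i] = None
                        continue
                    # rule 2 is checked against the amplitude each candidate
                    # action would command, so a width decrease can never
                    # take effect at the ceiling
                    ch = channels[i]
                    adm = [
                        k
                        for k, act in enumerate(ACTIONS)
                        if is_admissible(
                            ch,
                            act,
                            limits,
                            ch.baseline_amplitude_mA + act.alpha * limits.step_a_mA + u
                            >= ma - 1e-9,
                            initial_amps[i],
                        )
                    ]
                    current_actions[i] = select_action(
                        table, epsilon, adm, rng_agent,
                        prefer_noop_on_tie=False,
                    )

        # build commands and per-tick rewards
        sv = StateVector(theta_deg=meas.theta_deg, mean_cadence_error_rpm=mean_err)
        commands = []
        row = [
            t,
            episode,
            epsilon if use_agent else float("nan"),
            meas.theta_deg,
            meas.cadence_rpm,
            state.cadence_rpm,
            config.reference_rpm,
            err,
            mean_err,
            u,
            state.power_w,
        ]
        tick_reward = 0.0
        fitness = state.fitness or [1.0] * len(channels)
        for i, ch in enumerate(channels):
            idx = current_actions[i]
            action = ACTIONS[idx] if idx is not None else ACTIONS[NOOP_INDEX]
            a_eff = ch.baseline_amplitude_mA + action.alpha * limits.step_a_mA + u
            a_eff = min(max(a_eff, 0.0), ma)
            w_eff = ch.baseline_width_us + action.omega * limits.step_w_us
            w_eff = min(max(w_eff, limits.w_min_us), limits.w_max_us)
            active = ch.enabled and in_window(meas.theta_deg, ch)
            commands.append(
                StimulationCommand(
                    channel_id=ch.channel_id,
                    amplitude_mA=a_eff if ch.enabled else 0.0,
                    width_us=w_eff,
                    frequency_hz=ch.frequency_hz,
                    active=active,
                )
            )
            if use_agent and ch.enabled and idx is not None:
                r = instantaneous_reward(sv, ch, action, u, reward_params, limits)
                if active:
                    inter_sum[i] += r
                    inter_cnt[i] += 1
            else:
                r = 0.0
            tick_reward += r
            row.extend(
                [
                    float(active),
                    a_eff if ch.enabled else 0.0,
                    w_eff,
                    ch.frequency_hz,
                    float(idx) if idx is not None else float("nan"),
                    r,
                    fitness[i] if i < len(fitness) else 1.0,
                ]
            )
        total_reward += tick_reward
        total_abs_error += abs(err)
        distance_m += state.cadence_rpm / 60.0 * dt * env_cfg.meters_per_rev
        rows.append(row)

        state = env_step(state, commands, env_cfg, dt, rng=rng_env)

    columns = list(BASE_COLUMNS)
    for i in range(len(channels)):
        columns.extend(channel_columns(i))
    data = pd.DataFrame(rows, columns=columns)
    header = {
        "config": config.to_dict(),
        "seed": config.seed,
        "label": config.label or config.scenario,
        "online": {
            "total_reward": total_reward,
            "total_abs_error": total_abs_error,
            "distance_m": distance_m,
            "final_epsilon": epsilon if use_agent else None,
            "episodes_completed": episode,
        },
    }
    return SessionLog(header=header, data=data)


def replace_unwrapped(state, unwrapped_deg):
    s = dataclasses.replace(state)
    s.theta_unwrapped_deg = unwrapped_deg
    return s


def _validate(channels: Sequence[ChannelConfig], limits: ParameterLimits) -> None:
    for ch in channels:
        if not (0.0 <= ch.baseline_amplitude_mA <= limits.ma_mA):
            raise ValueError(
                f"channel {ch.channel_id}: baseline amplitude "
                f"{ch.baseline_amplitude_mA} mA outside [0, {limits.ma_mA}]"
            )
        if not (limits.w_min_us <= ch.baseline_width_us <= limits.w_max_us):
            raise ValueError(
                f"channel {ch.channel_id}: baseline width {ch.baseline_width_us} µs "
                f"outside [{limits.w_min_us}, {limits.w_max_us}]"
            )


def scenario_presets(duration_s: float = 3600.0, seed: int = 0) -> dict[str, SessionConfig]:
    """The six named session presets: {PI-only, 60%@.99, 40%@.99} × {M1, M2}.

    All channels start at 45 mA (right leg) and 50 mA (left leg), 500 µs and
    35 Hz, tracking 35 rpm; the agent step sizes are 2 mA and 20 µs with the
    pulse-parameter range Δa = 10 mA and widths bounded to [450, 600] µs.
    """
    presets: dict[str, SessionConfig] = {}
    for gear in ("m1", "m2"):
        env = env_preset(gear)
        common = dict(env=env, duration_s=duration_s, seed=seed)
        presets[f"pi_only_{gear}"] = SessionConfig(
            scenario="pi_only", label=f"only PI ({gear.upper()})", **common
        )
        presets[f"pi_rl_60_{gear}"] = SessionConfig(
            scenario="pi_rl",
            agent=AgentConfig(epsilon0=0.6, decay_rate=0.99),
            label=f"PI + RL 60%@.99 ({gear.upper()})",
            **common,
        )
        presets[f"pi_rl_40_{gear}"] = SessionConfig(
            scenario="pi_rl",
            agent=AgentConfig(epsilon0=0.4, decay_rate=0.99),
            label=f"PI + RL 40%@.99 ({gear.upper()})",
            **common,
        )
    return presets


# ---------------------------------------------------------------------------
# Config-file support
# ---------------------------------------------------------------------------

def session_config_from_dict(d: dict) -> SessionConfig:
    """Build a SessionConfig from plain nested dictionaries (YAML/JSON)."""
    d = dict(d)
    kwargs: dict = {}
    env = d.pop("env", "m1")
    if isinstance(env, str):
        kwargs["env"] = env_preset(env)
    else:
        env = dict(env)
        if "profiles" in env:
            from .env import MuscleProfile

            env["profiles"] = tuple(MuscleProfile(**p) for p in env["profiles"])
        if "recruitment" in env:
            from .env import Recruitment

            env["recruitment"] = Recruitment(**env["recruitment"])
        if "fatigue" in env:
            from .env import FatigueParams

            env["fatigue"] = FatigueParams(**env["fatigue"])
        kwargs["env"] = EnvConfig(**env)
    if "agent" in d:
        agent = dict(d.pop("agent"))
        if "reward" in agent:
            agent["reward"] = RewardParams(**agent["reward"])
        kwargs["agent"] = AgentConfig(**agent)
    if "limits" in d:
        kwargs["limits"] = ParameterLimits(**d.pop("limits"))
    if "channels" in d:
        kwargs["channels"] = tuple(ChannelConfig(**c) for c in d.pop("channels"))
    if "pi" in d:
        pi_cfg = d.pop("pi")
        kwargs["kp"] = pi_cfg.get("kp", pi_mod.DEFAULT_KP)
        kwargs["ki"] = pi_cfg.get("ki", pi_mod.DEFAULT_KI)
        kwargs["anti_windup"] = pi_cfg.get("anti_windup", True)
    kwargs.update(d)
    return SessionConfig(**kwargs)


def load_session_config(path) -> SessionConfig:
    import yaml

    with open(path) as fh:
        return session_config_from_dict(yaml.safe_load(fh))
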