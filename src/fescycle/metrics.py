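"""Evaluation quantities computed from 10-Hz session logs.

All metrics operate on the CSV/DataFrame log produced by
:func:`fescycle.session.run_session` (or a log recorded elsewhere with the
same schema), so any saved session can be re-analysed offline: the
moving-average cadence error, the summed injected charge of all channels,
accumulated reward and accumulated absolute cadence error, time to
amplitude saturation and a per-session summary (distance, duration, average
speed, average crank power).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulation import pulse_charge_rate

__all__ = [
    "SessionSummary",
    "moving_average",
    "stimulation_cost",
    "accumulated_series",
    "windowed_rate",
    "summarize",
    "time_to_amplitude_saturation",
]


@dataclass(frozen=True)
class SessionSummary:
    """Session totals in the style of a ride report.

    ``avg_power_w`` is an explicit proxy — the mean mechanical power of the
    simulated crank — not a calibrated wattage.
    """

    label: str
    distance_m: float
    duration_s: float
    avg_speed_kmh: float
    avg_power_w: float
    sd_power_w: float


def _channel_ids(log: pd.DataFrame) -> list[int]:
    ids = sorted(
        int(m.group(1))
        for c in log.columns
        if (m := re.fullmatch(r"ch(\d+)_amplitude_mA", c))
    )
    return ids


def moving_average(series, window: int) -> np.ndarray:
    """Trailing moving average with a partial-prefix convention.

    For the first ``k < window`` samples the mean of the available ``k`` is
    returned, so downstream cumulative plots start at t = 0 instead of
    emitting missing values.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


def stimulation_cost(log: pd.DataFrame, smooth_window: int | None = None) -> np.ndarray:
    """Per-tick total charge rate (µC/s) summed over the active channels.

    A channel contributes ``amplitude × width × frequency`` only while its
    on-flag is set (crank inside its stimulation window).  Pass
    ``smooth_window=100`` for the window-100 presentation smoothing.
    """
    total = np.zeros(len(log), dtype=float)
    for i in _channel_ids(log):
        on = log[f"ch{i}_on"].to_numpy(dtype=float)
        amp = log[f"ch{i}_amplitude_mA"].to_numpy(dtype=float)
        width = log[f"ch{i}_width_us"].to_numpy(dtype=float)
        freq = log[f"ch{i}_frequency_hz"].to_numpy(dtype=float)
        total += on * amp * width * freq * 1e-3
    if smooth_window is not None:
        total = moving_average(total, smooth_window)
    return total


def _per_tick(log: pd.DataFrame, field: str) -> np.ndarray:
    if field == "reward":
        vals = np.zeros(len(log), dtype=float)
        for i in _channel_ids(log):
            vals += log[f"ch{i}_reward"].to_numpy(dtype=float)
        return vals
    if field == "abs_error":
        if "cadence_error_rpm" in log.columns:
            err = log["cadence_error_rpm"].to_numpy(dtype=float)
        else:
            err = (log["reference_rpm"] - log["cadence_rpm"]).to_numpy(dtype=float)
        return np.abs(err)
    raise ValueError(f"unknown field {field!r}; expected 'reward' or 'abs_error'")


def accumulated_series(log: pd.DataFrame, field: str) -> np.ndarray:
    """Running sum over ticks of the per-tick reward (summed across channels)
    or of the absolute cadence error."""
    return np.cumsum(_per_tick(log, field))


def windowed_rate(log: pd.DataFrame, field: str, window: int = 100) -> np.ndarray:
    """Moving-average per-tick rate of the same quantities.

    Unlike the cumulative sum — which can never decrease while per-tick
    rewards are non-negative — this windowed rate can fall once tracking
    degrades, which is the natural reading of a reward curve that "starts to
    decrease" after amplitude saturation.
    """
    return moving_average(_per_tick(log, field), window)


def summarize(log: pd.DataFrame, meters_per_rev: float, label: str = "") -> SessionSummary:
    """Distance/duration/speed/power summary of one session log.

    Distance integrates the crank cadence (the true simulated cadence when
    logged, otherwise the measured one) times the gear-dependent distance
    per crank revolution.
    """
    t = log["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        duration = 0.0
        dt = 0.0
    else:
        dt = float(t[1] - t[0])
        duration = float(t[-1] - t[0]) + dt
    cad_col = "cadence_true_rpm" if "cadence_true_rpm" in log.columns else "cadence_rpm"
    cadence = log[cad_col].to_numpy(dtype=float)
    distance = float(np.sum(cadence / 60.0 * dt) * meters_per_rev)
    speed_kmh = distance / duration * 3.6 if duration > 0 else 0.0
    if "power_w" in log.columns:
        p = log["power_w"].to_numpy(dtype=float)
        avg_p, sd_p = float(np.mean(p)), float(np.std(p))
    else:
        avg_p = sd_p = math.nan
    return SessionSummary(
        label=label,
        distance_m=distance,
        duration_s=duration,
        avg_speed_kmh=speed_kmh,
        avg_power_w=avg_p,
        sd_power_w=sd_p,
    )


def time_to_amplitude_saturation(
    log: pd.DataFrame,
    threshold_mA: float = 100.0,
    sustain_s: float = 5.0,
) -> float:
    """First time (s) any channel's effective amplitude reaches the ceiling
    and stays there for ``sustain_s``; ``inf`` if it never saturates."""
    t = log["t_s"].to_numpy(dtype=float)
    if len(t) == 0:
        return math.inf
    amps = np.column_stack(
        [log[f"ch{i}_amplitude_mA"].to_numpy(dtype=float) for i in _channel_ids(log)]
    )
    sat = np.max(amps, axis=1) >= threshold_mA - 1e-9
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.1
    need = max(1, round(sustain_s / dt))
    run = 0
    for k, flag in enumerate(sat):
        run = run + 1 if flag else 0
        if run >= need:
            return float(t[k - need + 1])
    return math.inf
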