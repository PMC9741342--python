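"""Figure panels for session logs: cadence tracking, summed pulse
parameters, injected charge and accumulated reward/error."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import accumulated_series, moving_average, stimulation_cost, windowed_rate

__all__ = ["plot_session", "save_session_figures"]


def _channel_ids(log: pd.DataFrame) -> list[int]:
    import re

    return sorted(
        int(m.group(1))
        for c in log.columns
        if (m := re.fullmatch(r"ch(\d+)_amplitude_mA", c))
    )


def plot_session(log: pd.DataFrame, title: str = ""):
    """Three stacked panels mirroring the session report layout:
    cadence tracking, summed amplitude + width, smoothed summed charge."""
    import matplotlib.pyplot as plt

    t_min = log["t_s"].to_numpy() / 60.0
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)

    ax = axes[0]
    ax.plot(t_min, log["cadence_rpm"], lw=0.5, label="measured")
    if "cadence_true_rpm" in log.columns:
        ax.plot(t_min, log["cadence_true_rpm"], lw=0.8, label="true")
    ax.plot(t_min, log["reference_rpm"], "k--", lw=1, label="reference")
    ax.set_ylabel("cadence (rpm)")
    ax.legend(loc="lower left", fontsize=8)

    ids = _channel_ids(log)
    amp_sum = np.sum([log[f"ch{i}_amplitude_mA"].to_numpy() for i in ids], axis=0)
    width_sum = np.sum([log[f"ch{i}_width_us"].to_numpy() for i in ids], axis=0)
    ax = axes[1]
    ax.plot(t_min, amp_sum, label="Σ amplitude (mA)")
    ax2 = ax.twinx()
    ax2.plot(t_min, width_sum, color="tab:orange", label="Σ width (µs)")
    ax.set_ylabel("Σ amplitude (mA)")
    ax2.set_ylabel("Σ width (µs)")

    ax = axes[2]
    ax.plot(t_min, stimulation_cost(log, smooth_window=100))
    ax.set_ylabel("Σ charge rate (µC/s)")
    ax.set_xlabel("time (min)")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_learning(log: pd.DataFrame, title: str = ""):
    """Accumulated reward / |error| plus the windowed reward rate variant."""
    import matplotlib.pyplot as plt

    t_min = log["t_s"].to_numpy() / 60.0
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    axes[0].plot(t_min, accumulated_series(log, "reward"))
    axes[0].set_ylabel("accumulated reward")
    axes[1].plot(t_min, accumulated_series(log, "abs_error"))
    axes[1].set_ylabel("accumulated |error| (rpm)")
    axes[2].plot(t_min, windowed_rate(log, "reward", window=100))
    axes[2].set_ylabel("reward rate (window 100)")
    axes[2].set_xlabel("time (min)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_session_figures(log: pd.DataFrame, outdir, prefix: str = "session") -> list[str]:
    """Write the tracking and learning figures as PNGs; returns the paths."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fig in (
        ("tracking", plot_session(log, prefix)),
        ("learning", plot_learning(log, prefix)),
    ):
        path = outdir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=120)
        paths.append(str(path))
    import matplotlib.pyplot as plt

    plt.close("all")
    return paths
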