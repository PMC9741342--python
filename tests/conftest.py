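import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fescycle import ChannelConfig, ParameterLimits

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def limits() -> ParameterLimits:
    """Protocol limits: 100 mA cap, widths 450-600 µs, steps 2 mA / 20 µs."""
    return ParameterLimits()


@pytest.fixture
def limits_ka1() -> ParameterLimits:
    """Limits with the 1 mA amplitude step of the worked example."""
    return ParameterLimits(step_a_mA=1.0)


@pytest.fixture
def channel() -> ChannelConfig:
    return ChannelConfig(
        channel_id=2,
        muscle_label="HAM R",
        baseline_amplitude_mA=45.0,
        baseline_width_us=500.0,
        frequency_hz=35.0,
        theta_start_deg=0.0,
        theta_end_deg=360.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221124)


def make_log(
    n_ticks: int,
    n_channels: int = 1,
    dt: float = 0.1,
    cadence: float = 35.0,
    reference: float = 35.0,
    amplitude: float = 45.0,
    width: float = 500.0,
    frequency: float = 35.0,
    on: float = 1.0,
    reward: float = 0.0,
) -> pd.DataFrame:
    """Minimal synthetic session-log frame following the 10-Hz schema."""
    t = np.arange(n_ticks) * dt
    data = {
        "t_s": t,
        "episode": np.zeros(n_ticks, dtype=int),
        "epsilon": np.full(n_ticks, 0.6),
        "theta_deg": (t * cadence * 6.0) % 360.0,
        "cadence_rpm": np.full(n_ticks, cadence),
        "cadence_true_rpm": np.full(n_ticks, cadence),
        "reference_rpm": np.full(n_ticks, reference),
        "cadence_error_rpm": np.full(n_ticks, reference - cadence),
        "mean_error_rpm": np.full(n_ticks, reference - cadence),
        "pi_u_mA": np.zeros(n_ticks),
        "power_w": np.zeros(n_ticks),
    }
    for i in range(n_channels):
        data[f"ch{i}_on"] = np.full(n_ticks, on)
        data[f"ch{i}_amplitude_mA"] = np.full(n_ticks, amplitude)
        data[f"ch{i}_width_us"] = np.full(n_ticks, width)
        data[f"ch{i}_frequency_hz"] = np.full(n_ticks, frequency)
        data[f"ch{i}_action"] = np.full(n_ticks, np.nan)
        data[f"ch{i}_reward"] = np.full(n_ticks, reward)
        data[f"ch{i}_fitness"] = np.ones(n_ticks)
    return pd.DataFrame(data)


@pytest.fixture
def log_factory():
    return make_log
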