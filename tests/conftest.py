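import datetime as dt

import numpy as np
import pytest

from phaseswing import AnalysisConfig, EEGSession


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def grid(analysis_config):
    return analysis_config.grid


def make_session(
    n_samples: int = 7680,
    n_channels: int = 1,
    dd_score: int | None = 5,
    rate: float = 128.0,
    participant: str = "P",
    signal: np.ndarray | None = None,
    day: int = 1,
) -> EEGSession:
    """Minimal session factory for QC/IO tests (flat non-zero signal)."""
    if signal is None:
        signal = np.ones((n_channels, n_samples))
    labels = tuple(f"CH{i + 1}" for i in range(signal.shape[0]))
    return EEGSession(
        participant_id=participant,
        session_time=dt.datetime(2024, 1, day, 9, 0),
        signal=signal,
        channel_labels=labels,
        sampling_rate=rate,
        dd_score=dd_score,
    )


@pytest.fixture(scope="session")
def planted_jump_session(analysis_config):
    """Clean oscillation at the grid frequency nearest 10 Hz with 30 planted
    pi phase jumps; returns (session-like arrays, jump times, grid row)."""
    grid = analysis_config.grid
    row = grid.nearest_index(10.0)
    f0 = grid.as_array()[row]
    rate = 128.0
    t = np.arange(0, 60, 1 / rate)
    jump_times = 3.0 + 1.8 * np.arange(30)          # inside the trimmed region
    offset = np.zeros(t.size)
    np.add.at(offset, (jump_times * rate).round().astype(int), np.pi)
    x = np.cos(2 * np.pi * f0 * t + np.cumsum(offset))
    return x, jump_times, row, f0, rate
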