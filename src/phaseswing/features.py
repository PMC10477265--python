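"""Phase-resetting features: RAS, NA, their means, reset events, and PRR.

The relative angular speed

    RAS_f(t) = (phi_f(t) - phi_f(t - dt)) / (2*pi*f*dt) - 1

measures how much faster or slower the phase advances than a pure sinusoid
at the analysis frequency f; 0 means perfect agreement.  Because phase is
restricted to (-pi, pi], the one-sample difference is wrap-corrected: when
phi_f(t) - phi_f(t - dt) - 2*pi*f*dt falls below -pi, 2*pi is added to the
numerator, and when it exceeds +pi, 2*pi is subtracted.

A phase-resetting event is declared at sample t when the wavelet amplitude
is at a strict local minimum, A_f(t) < A_f(t - dt) and A_f(t) < A_f(t + dt),
and simultaneously |RAS_f(t) - MRAS_f| exceeds a threshold (0.05 by
default).  The phase resetting rate (PRR) is the number of such events per
oscillation cycle: count / (analysed duration * f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnalysisConfig, EEGSession, FrequencyGrid, TFRDecomposition
from .tfr import decompose_session

__all__ = [
    "ResetEvent",
    "relative_angular_speed",
    "normalised_amplitude",
    "mean_features",
    "reset_mask",
    "detect_resets",
    "phase_resetting_rate",
    "compute_feature_table",
    "session_features",
]


@dataclass(frozen=True)
class ResetEvent:
    """One detected phase-resetting event."""

    channel: str
    frequency: float       # Hz
    time: float            # seconds, on the trimmed axis
    ras_deviation: float   # RAS(t) - MRAS_f at the event sample


# ---------------------------------------------------------------------------
# Elementary series
# ---------------------------------------------------------------------------

def relative_angular_speed(
    phase: np.ndarray, f: float | np.ndarray, dt: float
) -> np.ndarray:
    """RAS along the last axis; output is one sample shorter than the input.

    Each value is aligned to the *later* sample of its phase pair.  ``f`` may
    be a scalar or an array broadcastable against ``phase`` without its time
    axis (e.g. per-frequency values for a (n_freqs, n_times) phase array).
    """
    phase = np.asarray(phase, float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = np.asarray(f, float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    nominal = 2.0 * np.pi * f * dt                    # expected phase advance
    nominal = np.expand_dims(nominal, -1) if nominal.ndim else nominal
    d = np.diff(phase, axis=-1)
    # wrap corrections: keep the numerator within +-pi of the nominal advance
    d = d + 2.0 * np.pi * (d - nominal < -np.pi)
    d = d - 2.0 * np.pi * (d - nominal > np.pi)
    return d / nominal - 1.0


def normalised_amplitude(amplitude: np.ndarray) -> np.ndarray:
    """Amplitude divided by its grand mean over time and frequency.

    Defined per channel: pass one channel's (n_freqs, n_times) array.  The
    result's grand mean is exactly 1.
    """
    amplitude = np.asarray(amplitude, float)
    m = amplitude.mean()
    if m == 0:
        raise ValueError("all-zero amplitude: degenerate channel")
    return amplitude / m


def mean_features(
    ras: np.ndarray, na: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Time means (MRAS, MNA) along the last axis."""
    if ras.shape[-1] == 0 or na.shape[-1] == 0:
        raise ValueError("empty series")
    return ras.mean(axis=-1), na.mean(axis=-1)


# ---------------------------------------------------------------------------
# Reset detection
# ---------------------------------------------------------------------------

def reset_mask(
    amplitude: np.ndarray,
    ras: np.ndarray,
    mras: np.ndarray,
    threshold: float,
    strict: bool = True,
) -> np.ndarray:
    """Boolean event mask over samples 1..n-2 of the trimmed series.

    ``amplitude`` has time length n, ``ras`` length n-1 (aligned to the later
    sample, so RAS at sample t is ``ras[..., t-1]``), ``mras`` is the
    per-(channel,)frequency mean with one fewer axis.  First and last samples
    can never be events (no two-sided neighbourhood).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = np.asarray(amplitude, float)
    if ras.shape[-1] != a.shape[-1] - 1:
        raise ValueError("ras must be one sample shorter than amplitude")
    lt = np.less if strict else np.less_equal
    minima = lt(a[..., 1:-1], a[..., :-2]) & lt(a[..., 1:-1], a[..., 2:])
    dev = ras[..., :-1] - np.expand_dims(np.asarray(mras, float), -1)
    mask = np.zeros(a.shape, dtype=bool)
    mask[..., 1:-1] = minima & (np.abs(dev) > threshold)
    return mask


def detect_resets(
    tfr: TFRDecomposition,
    ras: np.ndarray,
    mras: np.ndarray,
    threshold: float,
    strict: bool = True,
) -> list[ResetEvent]:
    """Reset events for a whole decomposition (channels x freqs x time)."""
    mask = reset_mask(tfr.amplitude, ras, mras, threshold, strict)
    dev = ras - np.expand_dims(np.asarray(mras, float), -1)
    freqs = tfr.grid.as_array()
    labels = list(tfr.channel_labels) or [
        str(c) for c in range(tfr.amplitude.shape[0])
    ]
    events = []
    for c, fi, t in zip(*np.nonzero(mask)):
        events.append(
            ResetEvent(
                channel=labels[c],
                frequency=float(freqs[fi]),
                time=float(tfr.time_axis[t]),
                ras_deviation=float(dev[c, fi, t - 1]),
            )
        )
    return events


def phase_resetting_rate(
    counts: np.ndarray, duration: float, grid: FrequencyGrid
) -> np.ndarray:
    """PRR = events per cycle = count / (duration * f).

    ``counts`` is (..., n_freqs); the frequency axis is last.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(counts, float) / (duration * grid.as_array())


# ---------------------------------------------------------------------------
# Per-session orchestration
# ---------------------------------------------------------------------------

def session_features(
    tfr: TFRDecomposition, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mras, mna, prr, n_resets) arrays of shape (n_channels, n_freqs)."""
    freqs = tfr.grid.as_array()
    dt = tfr.sampling_interval
    ras = relative_angular_speed(tfr.phase, freqs, dt)
    na = np.stack([normalised_amplitude(a) for a in tfr.amplitude])
    mras, mna = mean_features(ras, na)
    mask = reset_mask(
        tfr.amplitude, ras, mras, config.ras_threshold, config.strict_minima
    )
    counts = mask.sum(axis=-1)
    prr = phase_resetting_rate(counts, tfr.duration, tfr.grid)
    return mras, mna, prr, counts


def compute_feature_table(
    session: EEGSession, config: AnalysisConfig
) -> pd.DataFrame:
    """Full pipeline for one session -> long-format feature rows.

    Columns: participant, session, channel, frequency_hz, mras, mna, prr,
    n_resets, n_cycles (the last two are carried in memory; the on-disk
    format keeps the first seven).
    """
    tfr = decompose_session(session, config)
    mras, mna, prr, counts = session_features(tfr, config)
    freqs = tfr.grid.as_array()
    nch, nf = mras.shape
    labels = list(session.channel_labels)
    return pd.DataFrame(
        {
            "participant": session.participant_id,
            "session": session.session_id,
            "channel": np.repeat(labels, nf),
            "frequency_hz": np.tile(freqs, nch),
            "mras": mras.ravel(),
            "mna": mna.ravel(),
            "prr": prr.ravel(),
            "n_resets": counts.ravel(),
            "n_cycles": np.tile(tfr.duration * freqs, nch),
        }
    )
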