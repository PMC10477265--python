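"""Synthetic resting-EEG studies with planted reset--mood coupling.

Each simulated session is a sum of narrowband oscillators over a 1/f
background.  An oscillator at a *coupled* frequency undergoes Poisson phase
resets whose rate depends linearly on the session's standardized latent mood
score; a positive slope makes resets more frequent on worse-mood days (a
positive characteristic frequency) and a negative slope the reverse.  Each
reset is an instantaneous phase jump of magnitude uniform on [pi/2, pi]
(random sign), which produces both the amplitude notch and the angular-speed
excursion the detector looks for.  Channels share event times at coupled
frequencies up to a jitter of a couple of samples, mirroring the
multi-channel simultaneity of real resets; amplitude envelopes are slow
log-normal modulations so that amplitude minima also occur without resets
and the RAS conjunct of the detector is exercised as a genuine filter.

Mood scores are drawn as integers from a low-skewed discretised gamma
distribution on [0, 50] (most scores below 10, as in the study population).
The generator writes the same CSV/score-table formats the readers consume
and returns the planted ground truth for recovery tests.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage

from .io import (
    EPOC_X_MONTAGE,
    EEGSession,
    write_score_table,
    write_session_csv,
)

__all__ = [
    "SyntheticStudyConfig",
    "generate_session_signal",
    "generate_study",
    "write_study",
    "GRID_ALPHA_HZ",
    "GRID_LOWBETA_HZ",
    "GRID_THETA_HZ",
]

# Default-grid frequencies used as carriers (exact grid points, 32*2^(-m/10)).
GRID_THETA_HZ = 32.0 * 2.0 ** (-2.2)    # ~6.96 Hz
GRID_ALPHA_HZ = 32.0 * 2.0 ** (-1.7)    # ~9.85 Hz
GRID_LOWBETA_HZ = 32.0 * 2.0 ** (-1.2)  # ~13.93 Hz


def _default_coupling() -> dict[float, float]:
    # one positive and one negative characteristic frequency
    return {GRID_ALPHA_HZ: +0.5, GRID_LOWBETA_HZ: -0.5}


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the simulator.

    ``coupling`` maps an oscillator frequency to the slope (events/s per SD
    of mood) linking the standardized mood score to its reset rate; carriers
    without an entry reset at ``base_reset_rate`` regardless of mood.
    """

    n_sessions: int = 30
    n_channels: int = 14
    duration: float = 60.0          # seconds
    rate: float = 128.0             # Hz
    carrier_freqs: tuple[float, ...] = (GRID_THETA_HZ, GRID_ALPHA_HZ,
                                        GRID_LOWBETA_HZ)
    coupling: dict[float, float] = field(default_factory=_default_coupling)
    base_reset_rate: float = 1.5    # events/s at mood_z = 0
    mood_gamma_shape: float = 2.0   # discretised gamma, mean ~6, skewed low
    mood_gamma_scale: float = 3.0
    noise_exponent: float = 1.0     # 1/f spectral slope of the background
    snr: float = 3.0                # oscillation-to-noise RMS ratio
    seed: int = 0
    max_mood_z: float = 3.0         # rate nonnegativity enforced to this |z|
    jitter_samples: int = 2         # per-channel event-time jitter
    refractory: float = 0.25        # s; a reset is one episode, not a burst
    envelope_corr_time: float = 1.0  # seconds
    envelope_sd: float = 0.5        # log-amplitude SD

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.duration <= 0 or self.rate <= 0:
            raise ValueError("n_channels, duration and rate must be positive")
        f = np.asarray(self.carrier_freqs, float)
        if np.any(f < 2.0) or np.any(f > 32.0):
            raise ValueError("carrier frequencies must lie in [2, 32] Hz")
        unknown = set(self.coupling) - set(self.carrier_freqs)
        if unknown:
            raise ValueError(f"coupling at non-carrier frequencies {unknown}")
        worst = max((abs(s) for s in self.coupling.values()), default=0.0)
        if self.base_reset_rate - worst * self.max_mood_z < 0:
            raise ValueError(
                "base_reset_rate too small: reset rate would go negative "
                f"within |mood_z| <= {self.max_mood_z}"
            )
        if self.mood_gamma_shape <= 0 or self.mood_gamma_scale <= 0:
            raise ValueError("mood distribution parameters must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shape, n)
    return x / x.std()


def _slow_lognormal_envelope(
    n: int, rate: float, corr_time: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    g = scipy.ndimage.gaussian_filter1d(
        rng.standard_normal(n), sigma=corr_time * rate, mode="wrap"
    )
    g = (g - g.mean()) / g.std()
    return np.exp(sd * g)


def generate_session_signal(
    config: SyntheticStudyConfig,
    mood_z: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """One session's (n_channels, n_samples) signal and planted event times.

    Deterministic given the generator state: passing an int (or the config
    seed via ``rng=None``) yields byte-identical output across runs.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_samples
    t = np.arange(n) / config.rate
    osc = np.zeros((config.n_channels, n))
    planted: dict[float, np.ndarray] = {}

    for f in config.carrier_freqs:
        lam = max(0.0, config.base_reset_rate
                  + config.coupling.get(f, 0.0) * mood_z)
        n_ev = rng.poisson(lam * config.duration)
        times = np.sort(rng.uniform(0.0, config.duration, n_ev))
        # refractory thinning: jumps closer than one reset episode merge in
        # the wavelet domain and would be indistinguishable from one event
        kept = []
        last = -np.inf
        for ev in times:
            if ev - last >= config.refractory:
                kept.append(ev)
                last = ev
        times = np.asarray(kept)
        n_ev = times.size
        planted[f] = times
        jumps = rng.uniform(np.pi / 2, np.pi, n_ev) * rng.choice((-1.0, 1.0), n_ev)
        base_idx = np.minimum((times * config.rate).round().astype(int), n - 1)

        for c in range(config.n_channels):
            jitter = rng.integers(-config.jitter_samples,
                                  config.jitter_samples + 1, n_ev)
            idx = np.clip(base_idx + jitter, 0, n - 1)
            offset = np.zeros(n)
            np.add.at(offset, idx, jumps)
            offset = np.cumsum(offset)
            phi0 = rng.uniform(0.0, 2.0 * np.pi)
            env = _slow_lognormal_envelope(
                n, config.rate, config.envelope_corr_time,
                config.envelope_sd, rng,
            )
            osc[c] += env * np.cos(2.0 * np.pi * f * t + phi0 + offset)

    osc_rms = np.sqrt(np.mean(osc ** 2))
    signal = np.empty_like(osc)
    for c in range(config.n_channels):
        noise = _pink_noise(n, config.noise_exponent, rng)
        signal[c] = osc[c] + noise * (osc_rms / config.snr)
    return 10.0 * signal, planted  # ~tens of microvolts


def _draw_mood_scores(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> np.ndarray:
    for _ in range(8):
        raw = rng.gamma(config.mood_gamma_shape, config.mood_gamma_scale,
                        config.n_sessions)
        scores = np.clip(np.round(raw), 0, 50).astype(int)
        if np.ptp(scores) > 0:
            return scores
    raise ValueError(
        "mood distribution is degenerate: drawn scores have a single value"
    )


def generate_study(
    config: SyntheticStudyConfig,
) -> tuple[list[EEGSession], dict]:
    """Simulate a whole participant: sessions with DD scores + ground truth."""
    if config.n_sessions < 3:
        raise ValueError("need n_sessions >= 3")
    ss = np.random.SeedSequence(config.seed)
    score_rng = np.random.default_rng(ss.spawn(1)[0])
    session_seeds = ss.spawn(config.n_sessions)

    scores = _draw_mood_scores(config, score_rng)
    mood_z = (scores - scores.mean()) / scores.std()

    labels = (EPOC_X_MONTAGE if config.n_channels == len(EPOC_X_MONTAGE)
              else tuple(f"CH{i + 1}" for i in range(config.n_channels)))
    base_time = _dt.datetime(2024, 1, 1, 9, 0)
    sessions: list[EEGSession] = []
    event_times: list[dict[float, list[float]]] = []
    for i in range(config.n_sessions):
        rng = np.random.default_rng(session_seeds[i])
        signal, planted = generate_session_signal(config, float(mood_z[i]), rng)
        sessions.append(
            EEGSession(
                participant_id="SIM",
                session_time=base_time + _dt.timedelta(days=i),
                signal=signal,
                channel_labels=labels,
                sampling_rate=config.rate,
                dd_score=int(scores[i]),
            )
        )
        event_times.append({f: times.tolist() for f, times in planted.items()})

    ground_truth = {
        "coupling": dict(config.coupling),
        "base_reset_rate": config.base_reset_rate,
        "mood_scores": scores.tolist(),
        "mood_z": mood_z.tolist(),
        "event_times": event_times,
        "seed": config.seed,
    }
    return sessions, ground_truth


def write_study(
    sessions: list[EEGSession], ground_truth: dict, directory: str | Path
) -> Path:
    """Write sessions as per-channel CSVs + score table + ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        write_session_csv(s, directory)
        rows.append(
            {"participant_id": s.participant_id,
             "session_time": s.session_time.isoformat(),
             "dd_score": s.dd_score if s.dd_score is not None else "",
             "medicated": s.medicated, "notes": s.notes}
        )
    write_score_table(rows, directory / "scores.tsv")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1)
    return directory
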