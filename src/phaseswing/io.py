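"""Domain types, configuration, and file I/O for the phase-resetting pipeline.

The atomic analysis unit is a single resting-state EEG measurement session
(:class:`EEGSession`): ~60 s of eyes-closed multichannel EEG plus the
Depression--Dejection (DD) mood score reported at the same sitting.  Sessions
are read from EDF or from a plain per-channel CSV dialect, paired with a
delimited score table, and all downstream stages exchange a long-format
feature table (one row per session x channel x analysis frequency).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPOC_X_MONTAGE",
    "EEGSession",
    "FrequencyGrid",
    "TFRDecomposition",
    "AnalysisConfig",
    "SessionFormatError",
    "ChannelMismatchError",
    "read_session",
    "write_session_csv",
    "read_score_table",
    "write_score_table",
    "read_feature_table",
    "write_feature_table",
    "FEATURE_COLUMNS",
]

#: 14-channel consumer headset montage, 10-10 system positions, in device order.
EPOC_X_MONTAGE: tuple[str, ...] = (
    "AF3", "F3", "F7", "FC5", "T7", "P7", "O1",
    "AF4", "F4", "F8", "FC6", "T8", "P8", "O2",
)

#: Columns of the on-disk long-format feature table.
FEATURE_COLUMNS = (
    "participant", "session", "channel", "frequency_hz", "mras", "mna", "prr",
)


class SessionFormatError(ValueError):
    """A session file could not be parsed (names the offending record)."""


class ChannelMismatchError(ValueError):
    """Channel count/labels in a file disagree with the declared montage."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGSession:
    """One measurement: multichannel signal plus mood score and metadata.

    Parameters
    ----------
    participant_id : str
        Anonymous participant label.
    session_time : datetime
        Measurement timestamp; sessions are ordered by this within participant.
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    channel_labels : sequence of str
        10-10 position names, one per signal row.
    sampling_rate : float
        Nominal 128 Hz for the study device.
    dd_score : int or None
        Depression--Dejection score in [0, 50]; ``None`` when the
        questionnaire was not answered.
    """

    participant_id: str
    session_time: _dt.datetime
    signal: np.ndarray
    channel_labels: Sequence[str] = EPOC_X_MONTAGE
    sampling_rate: float = 128.0
    dd_score: int | None = None
    notes: str = ""
    medicated: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ChannelMismatchError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels are declared"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.dd_score is not None:
            self.dd_score = int(self.dd_score)
            if not 0 <= self.dd_score <= 50:
                raise ValueError(f"dd_score {self.dd_score} outside [0, 50]")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recorded duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def session_id(self) -> str:
        return f"{self.participant_id}_{self.session_time:%Y%m%dT%H%M%S}"


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmic analysis-frequency grid, fixed voices per octave.

    The default is 40 frequencies between 2 and 32 Hz at 10 voices per
    octave, anchored at 32 Hz and descending (stored ascending):
    ``f_k = 32 * 2**(-(39 - k)/10)`` for ``k = 0..39``, i.e. ~2.14 ... 32 Hz.
    """

    frequencies: tuple[float, ...]
    voices_per_octave: int = 10

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        if f.ndim != 1 or len(f) < 2:
            raise ValueError("grid needs at least two frequencies")
        if np.any(f < 2.0 - 1e-9) or np.any(f > 32.0 + 1e-9):
            raise ValueError("grid frequencies must lie in [2, 32] Hz")
        step = 2.0 ** (1.0 / self.voices_per_octave)
        ratios = f[1:] / f[:-1]
        if np.any(np.abs(ratios / step - 1.0) > 1e-9):
            raise ValueError(
                "consecutive frequency ratios must equal 2^(1/voices_per_octave)"
            )

    @classmethod
    def default(cls, n: int = 40, top: float = 32.0,
                voices_per_octave: int = 10) -> "FrequencyGrid":
        k = np.arange(n)
        f = top * 2.0 ** (-(n - 1 - k) / voices_per_octave)
        return cls(tuple(f), voices_per_octave)

    def __len__(self) -> int:
        return len(self.frequencies)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, float)

    def nearest_index(self, f: float) -> int:
        """Index of the grid point nearest *f* on a log scale."""
        return int(np.argmin(np.abs(np.log(self.as_array()) - math.log(f))))


@dataclass
class TFRDecomposition:
    """Per-channel wavelet phase and amplitude on the trimmed time axis."""

    phase: np.ndarray       # (n_channels, n_freqs, n_times), radians in (-pi, pi]
    amplitude: np.ndarray   # (n_channels, n_freqs, n_times), >= 0
    time_axis: np.ndarray   # seconds, offset by the edge trim
    grid: FrequencyGrid
    sampling_interval: float
    channel_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        if np.any(np.abs(self.phase) > np.pi + 1e-12):
            raise ValueError("phase outside (-pi, pi]")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    @property
    def duration(self) -> float:
        """Analysed (trimmed) duration in seconds."""
        return self.phase.shape[-1] * self.sampling_interval


@dataclass
class AnalysisConfig:
    """Pipeline constants; defaults are the study's printed values."""

    bandpass_range: tuple[float, float] = (1.0, 40.0)
    edge_trim: float = 1.5              # seconds removed from each end
    ras_threshold: float = 0.05         # |RAS - MRAS| bound for a reset event
    min_duration: float = 55.0          # seconds; shorter sessions excluded
    n_permutations: int = 10_000
    permutation_cc_bound: float = 0.5   # accepted shuffles have |r| <= this
    random_seed: int = 0
    wavelet_omega0: float = 6.0         # Morlet centre frequency (rad)
    strict_minima: bool = True          # reset requires a strict amplitude minimum
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)

    def __post_init__(self) -> None:
        low, high = self.bandpass_range
        if not 0 < low < high:
            raise ValueError("bandpass_range must satisfy 0 < low < high")
        for name in ("edge_trim", "ras_threshold", "min_duration",
                     "n_permutations", "wavelet_omega0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.permutation_cc_bound <= 1:
            raise ValueError("permutation_cc_bound must be in (0, 1]")

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"frequencies": list(self.grid.frequencies),
                     "voices_per_octave": self.grid.voices_per_octave}
        return d


# ---------------------------------------------------------------------------
# Session files
# ---------------------------------------------------------------------------

def _parse_session_stem(stem: str) -> tuple[str, _dt.datetime]:
    pid, _, stamp = stem.rpartition("_")
    if not pid:
        raise SessionFormatError(
            f"cannot infer participant/session from file name {stem!r}; "
            "expected '<participant>_<YYYYmmddTHHMMSS>'"
        )
    try:
        when = _dt.datetime.strptime(stamp, "%Y%m%dT%H%M%S")
    except ValueError as exc:
        raise SessionFormatError(f"bad session timestamp in {stem!r}: {exc}") from exc
    return pid, when


def read_session(
    path: str | Path,
    score_table: pd.DataFrame | None = None,
    *,
    participant_id: str | None = None,
    session_time: _dt.datetime | None = None,
    expected_labels: Sequence[str] | None = None,
    sampling_rate: float = 128.0,
) -> EEGSession:
    """Read one session from EDF or per-channel CSV and attach its DD score.

    The CSV dialect is one file per session: a header row of channel labels,
    then one sample per line, values in microvolts.  ``participant_id`` and
    ``session_time`` default to being parsed from a file stem of the form
    ``<participant>_<YYYYmmddTHHMMSS>``.  A session absent from the score
    table yields ``dd_score=None`` rather than an error.
    """
    path = Path(path)
    if participant_id is None or session_time is None:
        pid, when = _parse_session_stem(path.stem)
        participant_id = participant_id or pid
        session_time = session_time or when

    if path.suffix.lower() == ".edf":
        labels, signal, sampling_rate = _read_edf(path)
    else:
        labels, signal = _read_session_csv(path)

    if expected_labels is not None:
        if len(labels) != len(expected_labels):
            raise ChannelMismatchError(
                f"{path.name}: file has {len(labels)} channels, "
                f"{len(expected_labels)} expected"
            )
        if set(labels) != set(expected_labels):
            raise ChannelMismatchError(
                f"{path.name}: channel labels {labels} do not match the "
                f"declared montage {list(expected_labels)}"
            )
        order = [labels.index(c) for c in expected_labels]
        signal = signal[order]
        labels = list(expected_labels)

    dd, medicated, notes = None, False, ""
    if score_table is not None:
        row = _lookup_score(score_table, participant_id, session_time)
        if row is not None:
            dd = row.get("dd_score")
            dd = None if pd.isna(dd) else int(dd)
            medicated = bool(row.get("medicated", False))
            notes = "" if pd.isna(row.get("notes", "")) else str(row.get("notes", ""))

    return EEGSession(
        participant_id=participant_id,
        session_time=session_time,
        signal=signal,
        channel_labels=list(labels),
        sampling_rate=sampling_rate,
        dd_score=dd,
        medicated=medicated,
        notes=notes,
    )


def _read_session_csv(path: Path) -> tuple[list[str], np.ndarray]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise SessionFormatError(f"{path.name}: {exc}") from exc
    if df.empty:
        raise SessionFormatError(f"{path.name}: no samples")
    try:
        signal = df.to_numpy(dtype=float).T  # channels x samples
    except (TypeError, ValueError) as exc:
        bad = df.columns[df.dtypes == object].tolist()
        raise SessionFormatError(
            f"{path.name}: non-numeric values in column(s) {bad}"
        ) from exc
    return [str(c) for c in df.columns], signal


def _read_edf(path: Path) -> tuple[list[str], np.ndarray, float]:
    import mne  # heavy import; EDF path only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    return list(raw.ch_names), signal, float(raw.info["sfreq"])


def write_session_csv(session: EEGSession, directory: str | Path) -> Path:
    """Write the per-channel CSV dialect; returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{session.session_id}.csv"
    pd.DataFrame(session.signal.T, columns=list(session.channel_labels)).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read the per-session score table (TSV or CSV, sniffed by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", "session_time", "dd_score"}
    missing = required - set(df.columns)
    if missing:
        raise SessionFormatError(f"score table lacks columns {sorted(missing)}")
    df["session_time"] = pd.to_datetime(df["session_time"])
    df["dd_score"] = pd.to_numeric(df["dd_score"], errors="coerce").astype("Int64")
    if "medicated" not in df.columns:
        df["medicated"] = False
    if "notes" not in df.columns:
        df["notes"] = ""
    return df


def write_score_table(rows: Sequence[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def _lookup_score(table: pd.DataFrame, pid: str,
                  when: _dt.datetime) -> Mapping | None:
    hit = table[(table["participant_id"] == pid)
                & (table["session_time"] == pd.Timestamp(when))]
    if hit.empty:
        return None
    return hit.iloc[0].to_dict()


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format feature table as TSV.

    Values round-trip exactly through :func:`read_feature_table` (floats are
    written with shortest-exact repr).
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    table.loc[:, FEATURE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"feature table lacks columns {sorted(missing)}")
    return df
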