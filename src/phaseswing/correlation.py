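"""Feature-vs-mood correlation curves across a participant's sessions.

For each feature (MRAS, MNA, PRR), channel, and analysis frequency, the
Pearson correlation coefficient with the DD score is computed over the
participant's included sessions; Spearman's rank correlation is computed
alongside for reporting.  The curves of CC against log-frequency are the
object the swing statistic is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import FrequencyGrid

__all__ = [
    "CorrelationCurves",
    "correlation_curves",
    "reference_critical_cc",
    "feature_difference",
    "FEATURES",
]

FEATURES = ("mras", "mna", "prr")


@dataclass
class CorrelationCurves:
    """Pearson/Spearman CC per (feature, channel, frequency)."""

    participant: str
    channels: tuple[str, ...]
    grid: FrequencyGrid
    pearson: dict[str, np.ndarray]   # feature -> (n_channels, n_freqs)
    spearman: dict[str, np.ndarray]
    n: dict[str, np.ndarray] = field(default_factory=dict)  # pairwise sample sizes

    def curve(self, feature: str, channel: str,
              kind: str = "pearson") -> np.ndarray:
        ci = self.channels.index(channel)
        return (self.pearson if kind == "pearson" else self.spearman)[feature][ci]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        freqs = self.grid.as_array()
        for feat in self.pearson:
            for ci, ch in enumerate(self.channels):
                for fi, f in enumerate(freqs):
                    rows.append(
                        {"feature": feat, "channel": ch, "frequency_hz": f,
                         "r": self.pearson[feat][ci, fi],
                         "rs": self.spearman[feat][ci, fi],
                         "n": int(self.n[feat][ci, fi])}
                    )
        return pd.DataFrame(rows)


def _pairwise_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(pearson, spearman, n) with pairwise deletion of missing x."""
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0, 0.0, n  # degenerate feature: no linear association
    r = scipy.stats.pearsonr(xs, ys).statistic
    rs = scipy.stats.spearmanr(xs, ys).statistic
    return float(r), float(rs), n


def correlation_curves(
    features: pd.DataFrame, scores: pd.Series | dict
) -> CorrelationCurves:
    """CC of each feature with the DD score, per channel and frequency.

    ``features`` is the long-format table for one participant; ``scores``
    maps session id -> DD score.  Requires at least three sessions and
    non-constant scores.  Sessions with a missing feature value are dropped
    pairwise, with ``n`` reported per cell.
    """
    participants = features["participant"].unique()
    if len(participants) != 1:
        raise ValueError(f"expected one participant, got {list(participants)}")
    pid = participants[0]
    scores = pd.Series(scores, dtype=float)
    sessions = [s for s in features["session"].unique() if s in scores.index]
    if len(sessions) < 3:
        raise ValueError(
            f"participant {pid}: need >= 3 scored sessions, have {len(sessions)}"
        )
    y = scores.loc[sessions].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(
            f"participant {pid}: DD scores are constant; correlation undefined"
        )

    sub = features[features["session"].isin(sessions)]
    freqs = np.sort(sub["frequency_hz"].unique())
    voices = int(round(1.0 / np.log2(np.median(freqs[1:] / freqs[:-1]))))
    grid = FrequencyGrid(tuple(freqs), voices_per_octave=voices)
    channels = tuple(dict.fromkeys(sub["channel"]))  # montage order preserved

    pearson, spearman, ncell = {}, {}, {}
    for feat in FEATURES:
        # sessions x channels x freqs cube via pivot
        cube = (
            sub.pivot_table(index="session", columns=["channel", "frequency_hz"],
                            values=feat, sort=False)
            .reindex(index=sessions)
        )
        r = np.empty((len(channels), len(freqs)))
        rs = np.empty_like(r)
        nn = np.empty(r.shape, dtype=int)
        for ci, ch in enumerate(channels):
            for fi, f in enumerate(freqs):
                x = cube[(ch, f)].to_numpy(float)
                r[ci, fi], rs[ci, fi], nn[ci, fi] = _pairwise_corr(x, y)
        pearson[feat], spearman[feat], ncell[feat] = r, rs, nn

    return CorrelationCurves(
        participant=pid, channels=channels, grid=grid,
        pearson=pearson, spearman=spearman, n=ncell,
    )


def reference_critical_cc(n: int, alpha: float) -> float:
    """Two-sided critical |r| under the independent-normal reference model.

    Inverts r*sqrt((n-2)/(1-r^2)) ~ t(n-2): the bound such that |r| above it
    is significant at level ``alpha``.  For reference lines only — the DD
    scores need not satisfy the model's assumptions.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a critical correlation")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = scipy.stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def feature_difference(
    features: pd.DataFrame,
    f_pos: float,
    f_neg: float,
    channel: str,
    feature: str = "prr",
) -> pd.Series:
    """Per-session PRR(f_pos) - PRR(f_neg) for one channel.

    Combining rates at a positive and a negative characteristic frequency
    yields a stronger mood predictor than either frequency alone.
    """
    sub = features[features["channel"] == channel]
    freqs = np.sort(sub["frequency_hz"].unique())

    def _on_grid(f: float) -> float:
        i = int(np.argmin(np.abs(freqs - f)))
        if not np.isclose(freqs[i], f, rtol=1e-9, atol=1e-9):
            lo = freqs[freqs <= f].max() if np.any(freqs <= f) else None
            hi = freqs[freqs >= f].min() if np.any(freqs >= f) else None
            raise ValueError(
                f"{f} Hz is not on the grid; nearest grid points: {lo}, {hi}"
            )
        return float(freqs[i])

    fp, fn = _on_grid(f_pos), _on_grid(f_neg)
    pivot = sub.pivot_table(index="session", columns="frequency_hz",
                            values=feature, sort=False)
    return pivot[fp] - pivot[fn]
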