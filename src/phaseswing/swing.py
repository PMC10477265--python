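"""Swing magnitude of correlation curves and the constrained permutation test.

The correlation of the phase-resetting rate with mood often alternates
between large positive and large negative values as the analysis frequency
increases.  The *swing magnitude* quantifies this: over every three
consecutive alternating local extrema (p1, p2, p3) of a CC-vs-frequency
curve it takes |cc(p2) - (cc(p1) + cc(p3))/2|, maximises over triples, and
then over channels.  Since each CC lies in [-1, 1] the statistic lies in
[0, 2].

Significance is assessed by a constrained permutation test: DD-score vectors
are shuffled uniformly and a shuffle is *accepted* only when its Pearson
correlation with the original ordering lies within [-0.5, 0.5], so that null
permutations genuinely break the feature-score association; the statistic is
recomputed over all channels for each of the accepted shuffles (10,000 by
default), and p is the proportion of null statistics strictly greater than
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .correlation import CorrelationCurves, reference_critical_cc
from .io import AnalysisConfig

__all__ = [
    "Peak",
    "SwingTestResult",
    "find_alternating_peaks",
    "swing_magnitude",
    "swing_of_curves",
    "max_swing_over_channels",
    "characteristic_frequencies",
    "constrained_permutation_test",
    "draw_constrained_shuffles",
]


@dataclass(frozen=True)
class Peak:
    """A local extremum of a CC curve.

    ``kind`` is the extremum type: a local maximum is "positive" even when
    its value is below zero (permuted curves need not straddle zero).
    """

    index: int
    frequency: float
    cc: float
    kind: str  # "positive" (local max) or "negative" (local min)


@dataclass
class SwingTestResult:
    observed_swing: float
    best_channel: str
    swing_per_channel: dict[str, float]
    triple: tuple[Peak, ...]            # the extrema realising the maximum
    null_swings: np.ndarray
    null_mean: float
    null_sd: float
    p_value: float
    char_freqs_positive: tuple[float, ...]
    char_freqs_negative: tuple[float, ...]
    n_sessions: int
    seed: int
    acceptance_rate: float = np.nan
    feature: str = "prr"

    def summary(self) -> dict:
        p = self.p_value
        n_rep = len(self.null_swings)
        return {
            "n": self.n_sessions,
            "channel": self.best_channel,
            "max_swing": round(self.observed_swing, 3),
            "null_mean": round(self.null_mean, 3),
            "null_sd": round(self.null_sd, 3),
            "p_value": p if p > 0 else f"< {1.0 / n_rep:g}",
        }


# ---------------------------------------------------------------------------
# Peaks and the per-curve statistic
# ---------------------------------------------------------------------------

def _compress_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse runs of equal adjacent values to (value, start, end) arrays."""
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [values.size - 1]))
    return values[starts], starts, ends


def find_alternating_peaks(
    cc_curve: np.ndarray, frequencies: np.ndarray | None = None
) -> list[Peak]:
    """Local extrema of a curve, in frequency order, alternating in kind.

    Interior plateaus contribute one peak at the plateau midpoint sample;
    plateaus touching either end of the curve are not peaks (no two-sided
    neighbourhood).  A strictly monotone curve yields an empty list.
    """
    c = np.asarray(cc_curve, float)
    if c.size < 3:
        raise ValueError("curve must have at least 3 points")
    freqs = (np.arange(c.size, dtype=float)
             if frequencies is None else np.asarray(frequencies, float))
    vals, starts, ends = _compress_runs(c)
    peaks: list[Peak] = []
    for k in range(1, vals.size - 1):
        v = vals[k]
        if v > vals[k - 1] and v > vals[k + 1]:
            kind = "positive"
        elif v < vals[k - 1] and v < vals[k + 1]:
            kind = "negative"
        else:
            continue
        mid = int((starts[k] + ends[k]) // 2)  # plateau midpoint, stays on grid
        peaks.append(Peak(index=mid, frequency=float(freqs[mid]),
                          cc=float(v), kind=kind))
    return peaks


def swing_magnitude(peaks: list[Peak]) -> float:
    """Max over consecutive peak triples of |cc2 - (cc1 + cc3)/2|; 0 if < 3."""
    if len(peaks) < 3:
        return 0.0
    cc = np.array([p.cc for p in peaks])
    return float(np.max(np.abs(cc[1:-1] - 0.5 * (cc[:-2] + cc[2:]))))


@njit(cache=False)
def _swing_rows(curves):  # pragma: no cover - exercised via swing_of_curves
    m, length = curves.shape
    out = np.zeros(m)
    vals = np.empty(length)
    peaks = np.empty(length)
    for r in range(m):
        nc = 0
        i = 0
        while i < length:  # collapse equal-adjacent runs
            j = i
            while j + 1 < length and curves[r, j + 1] == curves[r, i]:
                j += 1
            vals[nc] = curves[r, i]
            nc += 1
            i = j + 1
        npk = 0
        for k in range(1, nc - 1):  # strict interior extrema alternate
            v = vals[k]
            if (v > vals[k - 1] and v > vals[k + 1]) or (
                v < vals[k - 1] and v < vals[k + 1]
            ):
                peaks[npk] = v
                npk += 1
        best = 0.0
        for k in range(npk - 2):
            d = abs(peaks[k + 1] - 0.5 * (peaks[k] + peaks[k + 2]))
            if d > best:
                best = d
        out[r] = best
    return out


def swing_of_curves(curves: np.ndarray) -> np.ndarray:
    """Swing magnitude of each row of a (n_curves, n_freqs) array.

    Batched fast path for the permutation null; agrees exactly with
    :func:`find_alternating_peaks` + :func:`swing_magnitude` per row.
    """
    curves = np.ascontiguousarray(np.atleast_2d(curves), dtype=float)
    return _swing_rows(curves)


def max_swing_over_channels(
    curves: CorrelationCurves, feature: str = "prr"
) -> tuple[str, float, tuple[Peak, ...]]:
    """Channel attaining the largest swing of its CC curve, with its triple.

    Ties break to the first channel in montage order.
    """
    freqs = curves.grid.as_array()
    best_channel, best_swing, best_triple = curves.channels[0], -1.0, ()
    for ch in curves.channels:
        peaks = find_alternating_peaks(curves.curve(feature, ch), freqs)
        s = swing_magnitude(peaks)
        if s > best_swing:
            cc = np.array([p.cc for p in peaks])
            if len(peaks) >= 3:
                k = int(np.argmax(np.abs(cc[1:-1] - 0.5 * (cc[:-2] + cc[2:]))))
                triple = tuple(peaks[k:k + 3])
            else:
                triple = ()
            best_channel, best_swing, best_triple = ch, s, triple
    return best_channel, float(best_swing), best_triple


def characteristic_frequencies(
    cc_curve: np.ndarray,
    frequencies: np.ndarray,
    bound: float,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Frequencies of large positive / large negative CC peaks.

    Positive characteristic frequencies are local maxima with cc >= bound;
    negative ones are local minima with cc <= -bound.
    """
    peaks = find_alternating_peaks(cc_curve, frequencies)
    pos = tuple(p.frequency for p in peaks
                if p.kind == "positive" and p.cc >= bound)
    neg = tuple(p.frequency for p in peaks
                if p.kind == "negative" and p.cc <= -bound)
    return pos, neg


# ---------------------------------------------------------------------------
# Constrained permutation test
# ---------------------------------------------------------------------------

def _feature_matrix(
    features: pd.DataFrame, scores: pd.Series, feature: str
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """(X, y, channels, freqs): X is sessions x channels x freqs."""
    sessions = [s for s in features["session"].unique() if s in scores.index]
    y = scores.loc[sessions].to_numpy(float)
    sub = features[features["session"].isin(sessions)]
    channels = list(dict.fromkeys(sub["channel"]))
    freqs = np.sort(sub["frequency_hz"].unique())
    pivot = (
        sub.pivot_table(index="session", columns=["channel", "frequency_hz"],
                        values=feature, sort=False)
        .reindex(index=sessions,
                 columns=pd.MultiIndex.from_product([channels, freqs]))
    )
    X = pivot.to_numpy(float).reshape(len(sessions), len(channels), len(freqs))
    return X, y, channels, freqs


def _corr_with_rows(S: np.ndarray, Xz: np.ndarray, y_norm: float) -> np.ndarray:
    """Pearson r of every row of S (permutations of y) with every column of Xz.

    Xz columns are centred and scaled to unit norm (zero columns for
    zero-variance features); rows of S all share y's mean and centred norm.
    """
    return (S @ Xz) / y_norm


def draw_constrained_shuffles(
    y: np.ndarray,
    bound: float,
    target: int,
    rng: np.random.Generator,
    max_unproductive: int = 1_000_000,
) -> tuple[np.ndarray, float]:
    """Uniform shuffles of ``y`` accepted iff their Pearson r with ``y`` is
    within ±``bound``; rejection sampling until ``target`` rows accepted.

    Returns ``(S, acceptance_rate)`` with S of shape (target, len(y)).
    Raises when the running acceptance rate is still below 1% after
    ``max_unproductive`` proposals (scores too structured for the bound).
    """
    y = np.asarray(y, float)
    yc = y - y.mean()
    y_norm = float(np.linalg.norm(yc))
    if y_norm == 0:
        raise ValueError("constant score vector: every shuffle is identical")
    yz = yc / y_norm
    accepted: list[np.ndarray] = []
    n_accepted = 0
    proposals = 0
    batch = max(256, min(8192, 2 * target))
    while n_accepted < target:
        S = rng.permuted(np.tile(y, (batch, 1)), axis=1)
        keep = np.abs((S @ yz) / y_norm) <= bound
        proposals += batch
        take = S[keep]
        if take.shape[0]:
            accepted.append(take[: target - n_accepted])
            n_accepted += accepted[-1].shape[0]
        if proposals >= max_unproductive and n_accepted / proposals < 0.01:
            raise RuntimeError(
                f"shuffle acceptance rate {n_accepted / proposals:.2%} after "
                f"{proposals} proposals; scores are too structured for the "
                f"|r| <= {bound} constraint"
            )
    return np.concatenate(accepted, axis=0), n_accepted / proposals


def constrained_permutation_test(
    features: pd.DataFrame,
    scores: pd.Series | dict,
    config: AnalysisConfig,
    feature: str = "prr",
    char_freq_alpha: float = 0.05,
) -> SwingTestResult:
    """Permutation test of the max-over-channels swing magnitude.

    Shuffled score vectors are drawn uniformly (with replacement from the
    permutation group) and kept only while their Pearson correlation with
    the original scores lies within ±``config.permutation_cc_bound``, until
    ``config.n_permutations`` have been accepted.  ``p`` is the proportion
    of accepted shuffles whose statistic strictly exceeds the observed one.
    """
    scores = pd.Series(scores, dtype=float)
    X, y, channels, freqs = _feature_matrix(features, scores, feature)
    n = y.size
    if n < 7:
        raise ValueError(f"need >= 7 sessions for the permutation test, have {n}")
    yc = y - y.mean()
    y_norm = float(np.linalg.norm(yc))
    if y_norm == 0:
        raise ValueError("DD scores are constant; the test is undefined")
    yz = yc / y_norm

    nch, nf = len(channels), len(freqs)
    flat = X.reshape(n, nch * nf)
    Xc = flat - flat.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = np.where(norms > 0, Xc / norms, 0.0)

    observed_r = (yz @ Xz).reshape(nch, nf)
    per_channel = swing_of_curves(observed_r)
    obs_curves = CorrelationCurves(
        participant=str(features["participant"].iloc[0]),
        channels=tuple(channels),
        grid=_grid_from(freqs),
        pearson={feature: observed_r},
        spearman={feature: np.full_like(observed_r, np.nan)},
        n={feature: np.full(observed_r.shape, n, dtype=int)},
    )
    best_channel, observed, triple = max_swing_over_channels(obs_curves, feature)

    rng = np.random.default_rng(config.random_seed)
    target = int(config.n_permutations)
    S, acceptance_rate = draw_constrained_shuffles(
        y, config.permutation_cc_bound, target, rng
    )

    null_r = _corr_with_rows(S, Xz, y_norm)          # (N, nch*nf)
    null_swings = swing_of_curves(
        null_r.reshape(target * nch, nf)
    ).reshape(target, nch).max(axis=1)

    p_value = float(np.mean(null_swings > observed))

    bound = reference_critical_cc(n, char_freq_alpha)
    ci = channels.index(best_channel)
    pos, neg = characteristic_frequencies(observed_r[ci], freqs, bound)

    return SwingTestResult(
        observed_swing=observed,
        best_channel=best_channel,
        swing_per_channel=dict(zip(channels, per_channel.tolist())),
        triple=triple,
        null_swings=null_swings,
        null_mean=float(null_swings.mean()),
        null_sd=float(null_swings.std(ddof=1)),
        p_value=p_value,
        char_freqs_positive=pos,
        char_freqs_negative=neg,
        n_sessions=n,
        seed=config.random_seed,
        acceptance_rate=acceptance_rate,
        feature=feature,
    )


def _grid_from(freqs: np.ndarray):
    from .io import FrequencyGrid

    voices = int(round(1.0 / np.log2(np.median(freqs[1:] / freqs[:-1]))))
    return FrequencyGrid(tuple(freqs), voices_per_octave=voices)
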