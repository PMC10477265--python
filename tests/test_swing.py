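import numpy as np
import pandas as pd
import pytest

from phaseswing import (
    AnalysisConfig,
    Peak,
    characteristic_frequencies,
    constrained_permutation_test,
    find_alternating_peaks,
    swing_magnitude,
    swing_of_curves,
    max_swing_over_channels,
)
from phaseswing.correlation import CorrelationCurves
from phaseswing.io import FrequencyGrid
from phaseswing.swing import draw_constrained_shuffles

from test_correlation import FREQS, feature_frame


def peaks_from(values, kinds=None):
    if kinds is None:
        kinds = ["positive" if i % 2 == 0 else "negative"
                 for i in range(len(values))]
    return [Peak(index=i, frequency=float(i), cc=float(v), kind=k)
            for i, (v, k) in enumerate(zip(values, kinds))]


class TestFindAlternatingPeaks:
    def test_worked_example(self):
        peaks = find_alternating_peaks([-0.1, 0.5, -0.2, 0.6, -0.3])
        assert [(p.index, p.kind) for p in peaks] == [
            (1, "positive"), (2, "negative"), (3, "positive")
        ]

    def test_monotone_curve_has_no_peaks(self):
        assert find_alternating_peaks(np.linspace(-1, 1, 10)) == []

    def test_kinds_alternate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            peaks = find_alternating_peaks(rng.standard_normal(40))
            kinds = [p.kind for p in peaks]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_interior_plateau_midpoint(self):
        peaks = find_alternating_peaks([0.0, 1.0, 1.0, 1.0, 0.0])
        assert len(peaks) == 1
        assert peaks[0].index == 2 and peaks[0].kind == "positive"

    def test_edge_plateau_is_not_a_peak(self):
        assert find_alternating_peaks([1.0, 1.0, 0.0, 0.5]) == [
            Peak(index=2, frequency=2.0, cc=0.0, kind="negative")
        ]

    def test_local_max_below_zero_is_positive_kind(self):
        peaks = find_alternating_peaks([-0.9, -0.3, -0.8])
        assert peaks[0].kind == "positive" and peaks[0].cc == -0.3

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            find_alternating_peaks([0.0, 1.0])


class TestSwingMagnitude:
    def test_study_peak_values(self):
        """The printed CC peaks of the strongest channel give a swing of
        ~1.465 (the study's 1.466 comes from unrounded inputs)."""
        s = swing_magnitude(peaks_from(
            [-0.69, 0.68, -0.80, 0.65],
            ["negative", "positive", "negative", "positive"],
        ))
        assert s == pytest.approx(1.465, abs=1e-9)

    def test_extremal_case(self):
        assert swing_magnitude(peaks_from([1.0, -1.0, 1.0])) == 2.0

    def test_fewer_than_three_peaks(self):
        assert swing_magnitude([]) == 0.0
        assert swing_magnitude(peaks_from([0.9, -0.9])) == 0.0

    def test_negation_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.uniform(-1, 1, rng.integers(3, 9))
            assert swing_magnitude(peaks_from(vals)) == pytest.approx(
                swing_magnitude(peaks_from(-vals))
            )

    def test_bounded_by_two_for_correlations(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s = swing_magnitude(peaks_from(rng.uniform(-1, 1, 7)))
            assert 0.0 <= s <= 2.0


class TestBatchedSwing:
    def test_agrees_exactly_with_per_curve_path(self):
        rng = np.random.default_rng(3)
        curves = rng.standard_normal((300, 40))
        # inject plateaus and constant rows
        curves[::7, 10:14] = curves[::7, 10][:, None]
        curves[5] = 0.3
        batched = swing_of_curves(curves)
        for row, expect in zip(curves, batched):
            peaks = find_alternating_peaks(row)
            assert swing_magnitude(peaks) == expect

    def test_constant_curve_swings_zero(self):
        assert swing_of_curves(np.zeros((1, 40)))[0] == 0.0


class TestMaxSwingOverChannels:
    def _curves(self, data):
        nch, nf = data.shape
        return CorrelationCurves(
            participant="A",
            channels=tuple(f"C{i}" for i in range(nch)),
            grid=FrequencyGrid(tuple(FREQS[:nf])),
            pearson={"prr": data},
            spearman={"prr": data},
            n={"prr": np.full(data.shape, 10)},
        )

    def test_single_channel(self):
        ch, s, triple = max_swing_over_channels(
            self._curves(np.array([[0.0, 0.6, -0.5, 0.7, -0.1]]))
        )
        assert ch == "C0" and s > 0 and len(triple) == 3

    def test_flat_channel_loses(self):
        data = np.zeros((2, 5))
        data[1] = [0.0, 0.6, -0.5, 0.7, -0.1]
        ch, s, _ = max_swing_over_channels(self._curves(data))
        assert ch == "C1"

    def test_tie_breaks_to_first_channel(self):
        data = np.tile([0.0, 0.6, -0.5, 0.7, -0.1], (3, 1))
        ch, _, _ = max_swing_over_channels(self._curves(data))
        assert ch == "C0"


class TestCharacteristicFrequencies:
    def test_all_small_curve_has_none(self):
        pos, neg = characteristic_frequencies(
            0.1 * np.sin(np.arange(20)), np.arange(20.0), 0.6
        )
        assert pos == () and neg == ()

    def test_alternating_curve_classified_by_extremum(self):
        """A curve shaped like the strongest channel's: negative peaks near
        7.3/14.5 Hz, positive near 10.3/20.5 Hz."""
        landmarks = [(7.3, -0.69), (10.3, 0.68), (14.5, -0.80), (20.5, 0.65)]
        curve = np.zeros(40)
        grid = FrequencyGrid.default()
        for f, cc in landmarks:
            curve[grid.nearest_index(f)] = cc
        # smooth zero background means each landmark is a local extremum
        pos, neg = characteristic_frequencies(curve, grid.as_array(), 0.6)
        assert [round(f, 1) for f in pos] == [10.6, 21.1]
        assert [round(f, 1) for f in neg] == [7.5, 14.9]

    def test_geometric_progression_recovered(self):
        grid = FrequencyGrid.default()
        f = grid.as_array()
        f0 = f[5]
        targets = [f0 * 2 ** (k / 2) for k in range(4)]   # half-octave spacing
        curve = np.zeros(40)
        signs = [1, -1, 1, -1]
        for tgt, s in zip(targets, signs):
            curve[grid.nearest_index(tgt)] = 0.8 * s
        pos, neg = characteristic_frequencies(curve, f, 0.6)
        recovered = sorted(pos + neg)
        for tgt, rec in zip(targets, recovered):
            assert abs(np.log2(rec / tgt)) <= 0.1 + 1e-9   # within one step


class TestConstrainedPermutationTest:
    def _setup(self, n=14, seed=0, structured=False):
        rng = np.random.default_rng(seed)
        prr = rng.standard_normal((n, 2, 12))
        df, sessions = feature_frame(prr, channels=("F7", "F8"))
        y = (np.arange(n, dtype=float) if structured
             else rng.integers(0, 12, n).astype(float))
        while np.ptp(y) == 0:
            y = rng.integers(0, 12, n).astype(float)
        return df, pd.Series(y, index=sessions)

    def test_accepted_shuffles_respect_cc_bound(self):
        y = np.arange(12.0)
        S, rate = draw_constrained_shuffles(y, 0.5, 300,
                                            np.random.default_rng(0))
        yz = (y - y.mean()) / np.linalg.norm(y - y.mean())
        r = (S @ yz) / np.linalg.norm(y - y.mean())
        assert np.all(np.abs(r) <= 0.5)
        assert S.shape == (300, 12)
        assert 0 < rate <= 1

    def test_overtight_bound_reports_acceptance_rate(self):
        # real-valued scores make an exactly-zero shuffle correlation
        # impossible, so a near-zero bound starves the sampler
        y = np.random.default_rng(1).random(8)
        with pytest.raises(RuntimeError, match="acceptance rate"):
            draw_constrained_shuffles(y, 1e-9, 10,
                                      np.random.default_rng(0),
                                      max_unproductive=100_000)

    def test_seeded_runs_are_bit_identical(self):
        df, y = self._setup()
        cfg = AnalysisConfig(n_permutations=200, random_seed=11)
        a = constrained_permutation_test(df, y, cfg)
        b = constrained_permutation_test(df, y, cfg)
        np.testing.assert_array_equal(a.null_swings, b.null_swings)
        assert a.p_value == b.p_value and a.observed_swing == b.observed_swing

    def test_observed_above_all_nulls_gives_p_zero(self):
        # plant a textbook swing so the observed statistic is extreme
        rng = np.random.default_rng(5)
        n = 20
        y = rng.normal(size=n)
        prr = rng.standard_normal((n, 1, 12)) * 0.05
        for col, sign in ((2, -1), (5, 1), (8, -1)):
            prr[:, 0, col] = sign * y
        df, sessions = feature_frame(prr)
        cfg = AnalysisConfig(n_permutations=300, random_seed=1)
        res = constrained_permutation_test(df, pd.Series(y, index=sessions), cfg)
        assert res.observed_swing > 1.5
        assert res.p_value == 0.0
        assert res.summary()["p_value"].startswith("<")

    def test_p_value_is_tail_proportion(self):
        df, y = self._setup(seed=3)
        cfg = AnalysisConfig(n_permutations=400, random_seed=2)
        res = constrained_permutation_test(df, y, cfg)
        assert res.p_value == np.mean(res.null_swings > res.observed_swing)
        assert len(res.null_swings) == 400

    def test_too_few_sessions_rejected(self):
        df, y = self._setup(n=6)
        with pytest.raises(ValueError, match=">= 7"):
            constrained_permutation_test(df, y, AnalysisConfig())

    def test_constant_scores_rejected(self):
        df, y = self._setup()
        with pytest.raises(ValueError, match="constant"):
            constrained_permutation_test(df, y * 0 + 4, AnalysisConfig())
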