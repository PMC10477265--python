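# Methods

## Analysis model

The pipeline treats one participant's repeated resting-state sessions as
the unit of inference: every statistic is intra-individual. A session is a
channels × samples matrix (µV, nominally 14 channels at 128 Hz for the
consumer headset montage AF3, F3, F7, FC5, T7, P7, O1, AF4, F4, F8, FC6,
T8, P8, O2) plus a Depression–Dejection (DD) score, an integer in [0, 50]
reported at the same sitting.

**Quality control.** A session is excluded iff the recording is shorter
than `min_duration` (55 s) or the DD score is missing; nothing else is
rejected — in particular there is no artifact rejection, and sessions
recorded under medication are kept and only flagged. Duration is measured
as samples/rate of the stored matrix (the data model requires finite
samples throughout, so a recording with gaps must be split before import).
The 55 s rule is applied to the raw recording, before edge trimming.

**Time–frequency decomposition.** Channels are bandpass filtered 1–40 Hz
with a zero-phase forward–backward Butterworth filter (order from
`buttord`, single-pass design 0.5 dB/20 dB so the two-pass response has
≤ 1 dB passband ripple and ≥ 40 dB attenuation at 0.5 Hz and 52 Hz).
Gustafsson initial conditions are used instead of pad-and-reflect because
reflective padding leaves passband-level transients within ~1/low s of the
signal ends. The wavelet transform is an analytic Morlet (Gabor) filter
bank applied in the FFT domain, ψ̂(ξ) = 2·exp(−(ξ−ω₀)²/2) for ξ > 0 with
ω₀ = 6 (config-exposed), scale s = ω₀/(2πf), and L1 normalisation so a
unit sinusoid yields unit amplitude at every analysis frequency — this
makes normalised amplitudes comparable across the grid. The frequency grid
is 40 points, 10 voices per octave, anchored at 32 Hz and stored
ascending (≈2.14 … 32 Hz); the anchoring convention is configurable
because printed peak locations in the source data are consistent with the
spacing but not with a unique anchor. The first and last 1.5 s of every
phase/amplitude series are discarded (edge distortion), leaving ~57 s.

**Features.** Relative angular speed is the one-sample phase advance
normalised by the expected advance 2πfΔt, minus 1, with ±2π corrections
keeping the numerator within ±π of the expected advance; exactly one
branch applies for any adjacent phase pair in (−π, π]. Normalised
amplitude divides by the grand mean over time and frequency *per channel*,
so its session-wide mean is 1 by construction. A reset event requires a
*strict* amplitude minimum (ties produce no event; they have measure zero
on real data) together with |RAS − MRAS| > 0.05, where MRAS is the
per-channel, per-frequency time mean over the same trimmed series. PRR
divides the event count by trimmed duration × frequency (events per
cycle); the trimmed duration is used because events are only observable
there. Threshold and strictness are config-exposed for sensitivity
analyses.

**Correlation curves.** Pearson r is the primary statistic; Spearman's rs
(average ranks for the frequent integer-score ties) is computed for
reporting. Sessions with a missing feature value are dropped pairwise with
per-cell n. Scores are used raw — no detrending over days. Constant score
vectors are an error, as every correlation is then undefined. Reference
significance bounds invert r√((n−2)/(1−r²)) ~ t(n−2); they assume
independent normal samples, which daily mood scores need not satisfy, and
are drawn for orientation only.

**Swing test.** Local extrema of a CC-vs-frequency curve are classified by
extremum type, not sign (a local maximum below zero is still a "positive
peak"): permuted curves need not straddle zero, and the statistic must be
defined on them. Interior plateaus contribute one peak at the plateau
midpoint sample; plateaus touching the curve ends have no two-sided
neighbourhood and yield nothing. The swing magnitude is the maximum over
consecutive extremum triples of |middle − mean(flanks)|, then over
channels (ties to the first channel in montage order); it lies in [0, 2]
for correlation curves and is invariant under curve negation. The
permutation null draws shuffles uniformly *with replacement* from the
permutation group (at n ≥ 14 duplicate shuffles are immaterial and
small-n behaviour stays well defined) and keeps one iff its Pearson
correlation with the original ordering is within ±0.5, until 10,000 are
accepted — the replicate count is fixed, not proposal-dependent, so tail
proportions down to 10⁻⁴ are meaningful. The sampler raises if fewer than
1% of a million proposals are acceptable. p is the proportion of null
statistics *strictly* greater than the observed; p = 0 is reported as
"< 1/N". Zero-variance feature cells contribute r = 0 rather than NaN in
both observed and null curves. The constraint makes the test mildly
anti-conservative — its long-run null rejection rate at the 0.05 level is
~6% (measured over 600 simulated null datasets) — a property of the
published procedure, not of this implementation.

## Synthetic studies

The generator emulates the structure the analysis is designed to detect,
not biophysics. Each channel is a sum of narrowband oscillators (defaults:
grid frequencies ≈6.96, 9.85, 13.93 Hz) with slowly varying log-normal
envelopes (correlation time 1 s, log-SD 0.5 — so amplitude minima occur
without resets and the RAS conjunct of the detector acts as a genuine
filter), over 1/f background noise at an oscillation-to-noise RMS ratio
of 3. Phase resets are Poisson events whose rate is
`base_reset_rate + coupling[f] · mood_z` (defaults 1.5 events/s and
slopes +0.5/−0.5 events/s per SD at 9.85/13.93 Hz, giving one positive and
one negative characteristic frequency); each reset jumps the phase by a
magnitude uniform on [π/2, π] with random sign. Channels share event times
at coupled frequencies up to ±2 samples of jitter, mirroring the
multi-channel simultaneity of real resets. Consecutive resets closer than
a 0.25 s refractory are merged: two jumps within one wavelet width are
indistinguishable from a single realignment episode, so unthinned events
would make the planted ground truth unrecoverable in principle (~24% of
events at 1.5 events/s). Mood scores are integers from a discretised
gamma(2, 3) clipped to [0, 50] — skewed low, most below 10, as in mildly
fluctuating healthy mood — and standardized within the study sample.

With these defaults a session's grand-mean PRR comes out ≈ 0.28 events
per cycle, near the ~0.25 level typical of real resting EEG under this
detector; the level is tuned by `base_reset_rate` and responds
monotonically at the carrier rows.

What the generator does *not* model: volume conduction and montage
geometry, ocular/muscle/mains artifacts, non-stationary background
spectra, and any biophysical mechanism linking mood to resets beyond the
linear rate coupling. Passing tests on synthetic studies therefore show
that the pipeline recovers the coupling structure it defines, not that
real EEG contains such structure.

## Numerical and design choices

- Wavelet edges: symmetric signal extension before the FFT, padded to at
  least six temporal SDs of the widest wavelet; the 1.5 s trim is applied
  regardless.
- The detector's localisation is limited by the wavelet's temporal SD
  (σ_t = ω₀/(2πf) ≈ 0.1 s at 10 Hz); planted-event recovery is therefore
  scored within ±2σ_t, and recovery of clean (noise-free) jumps is exact
  to ≤ 3 samples.
- The Morlet bandwidth (σ_f/f = 1/ω₀) spans ≈1.7 grid steps at 10 voices
  per octave, so CC peaks recovered through the full signal pipeline are
  intrinsically ±2 steps wide; sharper localisation claims are only
  testable on feature-level constructions.
- The batched swing statistic used in the permutation loop is a numba
  kernel; it agrees exactly (no tolerance) with the per-curve reference
  path, which is asserted in the suite.
- Problem sizes in the test suite and acceptance script are chosen for
  desk-scale runs: synthetic power/recovery studies use 30 sessions × 3
  channels (channel count only enters the statistic through a maximum, so
  fewer channels is conservative), calibration uses 600 null datasets of
  14 sessions × 14 channels at 500 replicates, and CLI smoke tests use 8
  sessions.
- Seeds: every stochastic component takes a `numpy` Generator or an
  integer seed; study generation derives per-session streams from a
  `SeedSequence`, so studies are reproducible bit-for-bit.

## Known limitations

- EDF reading goes through `mne` and expects standard continuous EDF/EDF+;
  vendor binary formats are out of scope, as is streaming acquisition.
- The exact wavelet parameterisation of the toolbox used to produce the
  original deposited recordings is not published; reproducing those
  numbers bit-for-bit may require matching its scale anchoring. Grid and
  ω₀ are configurable for that purpose.
- The questionnaire itself (administration, scoring) is out of scope; DD
  scores are consumed as given.
- No multiple-testing correction is applied across participants, and no
  cross-channel synchrony statistic is defined, matching the analysis
  being replicated.
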