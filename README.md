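# phaseswing

Intra-individual analysis of resting-state EEG **phase resetting** as a
marker of day-to-day **depressed mood**.

A person records ~60 s of eyes-closed EEG (14 channels, 128 Hz) once or
twice a day for a few weeks, each time also reporting a Depression–Dejection
(DD) mood score (0–50). `phaseswing` turns those sessions into
phase-resetting features, correlates them with mood *within* the
individual, and tests whether the correlation-vs-frequency curve swings
between large positive and negative values more than chance allows.

## Method

Each channel is bandpass filtered (1–40 Hz, zero phase) and decomposed with
an analytic Morlet wavelet into phase φ_f(t) and amplitude A_f(t) at 40
log-spaced frequencies f ∈ [2, 32] Hz (10 per octave); the first and last
1.5 s are discarded. From these:

- **Relative angular speed** — RAS_f(t) = (φ_f(t) − φ_f(t−Δt))/(2πfΔt) − 1,
  with ±2π wrap corrections whenever the raw phase difference leaves
  (2πfΔt − π, 2πfΔt + π]. RAS = 0 means the phase advances exactly at f.
- **Normalised amplitude** — NA_f(t) = A_f(t) / mean over t and f.
- **Phase-resetting events** — samples where A_f(t) is a strict local
  minimum *and* |RAS_f(t) − MRAS_f| > 0.05, where MRAS_f is the time mean.
- **Phase resetting rate (PRR)** — events per oscillation cycle:
  count / (duration × f).

Per channel and frequency, Pearson (and Spearman) correlation coefficients
(CC) of MRAS, MNA and PRR with the DD score are computed across sessions.
The **swing magnitude** summarises how strongly the CC(PRR) curve
alternates: over every three consecutive local extrema (p₁, p₂, p₃) of the
curve take |cc(p₂) − (cc(p₁)+cc(p₃))/2|, maximise over triples, then over
channels. Significance comes from a **constrained permutation test**:
score vectors are shuffled uniformly, kept only while their Pearson
correlation with the original ordering is within ±0.5, and the statistic is
recomputed for 10,000 accepted shuffles; p is the fraction of null
statistics exceeding the observed one. Frequencies where CC(PRR) attains a
large positive (negative) peak are the individual's positive (negative)
**characteristic frequencies**.

A synthetic-study generator produces multi-session recordings — narrowband
oscillators with Poisson phase resets whose rate is linearly coupled to a
latent mood score, slow log-normal envelopes, and a 1/f background — so the
whole pipeline is testable without any real recordings.

## Worked example

```python
import phaseswing as ps
from phaseswing.synthetic import SyntheticStudyConfig, generate_study, GRID_ALPHA_HZ
from phaseswing.cli import analyze_sessions, scores_by_session

cfg = SyntheticStudyConfig(n_sessions=30, n_channels=3, seed=42)  # ~9.8 Hz coupled +, ~13.9 Hz −
sessions, truth = generate_study(cfg)
acfg = ps.AnalysisConfig(random_seed=1, n_permutations=500)
features = analyze_sessions(sessions, acfg)
scores = scores_by_session(sessions)

curves = ps.correlation_curves(features, scores)
result = ps.constrained_permutation_test(features, scores, acfg)
print(result.summary())
```

prints

```
{'n': 30, 'channel': 'CH1', 'max_swing': 1.515, 'null_mean': 0.693,
 'null_sd': 0.12, 'p_value': '< 0.002'}
```

The observed swing (1.515) is the largest triple-alternation of the
CC(PRR)-vs-frequency curve over channels; the permutation null for
uncoupled scores sits at 0.69 ± 0.12, so the planted reset–mood coupling is
detected (p below the resolution of 500 replicates). The same objects
expose the curves (`curves.pearson["prr"]`), the characteristic frequencies
(`result.char_freqs_positive/negative`), and per-session combined
predictors (`ps.feature_difference`).

The same pipeline is available as a CLI:

```sh
phaseswing simulate study/ --sessions 30 --seed 42
phaseswing features study/ features.tsv
phaseswing correlate features.tsv study/scores.tsv cc.tsv
phaseswing swingtest features.tsv study/scores.tsv result.json --seed 1
phaseswing report features.tsv study/scores.tsv report/ --seed 1
```

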