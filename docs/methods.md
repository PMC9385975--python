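# Methods

This note documents the models and procedures implemented in `depspeech`,
the numerical choices behind them, what the synthetic data emulates, and
the known limitations.

## Acoustic front end

All low-level descriptors (LLDs) are computed per 30 ms Hamming-windowed
frame with a 10 ms step on peak-normalized mono audio (working rate
16 kHz by default; other rates are resampled on load). Frame count is
`floor((N − W)/H) + 1`; frame times are window centres; intervals are
half-open `[start, end)` so boundary frames belong to the right-hand
segment and are never double counted.

**Intensity** is `10·log10` of the mean squared windowed amplitude with a
1e−10 floor so silence stays finite.

**F0 and voicing.** Normalized autocorrelation per frame, peak searched
over 60–400 Hz (well inside the adult speaking range), refined by
parabolic interpolation. A frame is voiced when the peak exceeds 0.45 and
the frame is louder than −45 dB; voicing is additionally restricted to
annotated speech segments, and isolated single-frame voicing dropouts are
closed so that pulse analysis sees whole stretches. The defaults were
fixed against synthesized signals: a pure tone must track within ±1 Hz
with ≥ 95% voiced frames, seeded white noise must stay ≤ 10% voiced.

**Jitter and shimmer** use the *local* definitions: mean absolute
cycle-to-cycle difference of the period (amplitude) sequence divided by
the mean period (amplitude). Cycle marks are found per voiced stretch by
F0-guided peak picking on the **LPC residual** (inverse-filtered signal)
rather than the raw waveform: formant ringing overlaps successive cycles
and shifts raw-waveform peak positions and heights, which inflated
recovered shimmer by up to 18 percentage points at F0 = 220 Hz in
controlled synthesis; residual peaks recover synthesized jitter/shimmer
to within 0.02/0.34 pp. Stretches are split at phoneme boundaries
(the constant-expected-period search assumes locally stable F0), the
inverse-filter startup region is suppressed, and edge marks outside
[0.5, 2]× the stretch-median amplitude are trimmed — boundary
discontinuities otherwise inject spurious marks. Each stretch's scalar
jitter/shimmer is assigned to all its frames; stretches with fewer than
three usable marks stay undefined.

**Formants.** Autocorrelation-method LPC (Levinson–Durbin) on 0.97
pre-emphasized Hamming frames; candidates are polynomial roots inside the
unit circle with frequency in (90 Hz, Nyquist−50 Hz) and bandwidth below
700 Hz (from the root radius); the two lowest admissible frequencies
become F1/F2. The default order is `max(8, rate/1600 + 2)` — 12 at
16 kHz. A higher order (e.g. `rate/1000 + 2` = 18) is common for formant
tracking of low-pitched voices but starts modelling individual harmonics
of high-pitched voices as narrow spurious resonances: at F0 = 220 Hz it
reported the 880 Hz harmonic as F2 instead of the true 1750 Hz resonance,
while order 12 recovers both synthetic formants within ±26/±12 Hz across
F0 ∈ {100, 150, 220} Hz.

**MFCC.** Power spectrum (FFT of the next power of two above the window),
26 triangular mel filters spanning 20 Hz to min(8 kHz, Nyquist), log with
a 1e−12 floor, orthonormal DCT-II, coefficients c0–c12. Including c0
(rather than c1–c13) keeps an overall-energy term in the spectral block;
a gain change moves only c0, which the tests assert.

## The 286-feature vector

Each LLD track is summarized by six functionals — mean, population SD,
and the trimmed percentile ranges p99−p1, p95−p5, p85−p15, p75−p25
(linear interpolation between order statistics) — over fixed region
scopes:

| block | scopes | count |
|---|---|---|
| F0 | voiced | 6 |
| intensity | all vowels, whole speech | 12 |
| jitter | E, O, all vowels | 18 |
| shimmer | E, O, all vowels | 18 |
| F1, F2, BW1, BW2 | E, O, all vowels | 72 |
| 13 MFCC | all vowels, whole speech | 156 |
| articulation rate | whole speech | 1 |
| pause ratio | whole sample | 1 |
| ratio of transients | whole speech, whole sample | 2 |

282 LLD-derived features plus 4 timing features = 286, in a fixed,
named order (`<lld>_<scope>_<functional>`). A scope with fewer than two
defined frames flags its block missing (NaN) without changing the length;
missing entries are imputed with training-fold means inside the modelling
stage. "Ratio of transients" has no standard definition; it is
operationalized as the fraction of frames whose centre lies within
±20 ms (configurable) of any phoneme-segment boundary — a measure of
spectro-temporal transition density, and the highest-uncertainty feature
in the set. Articulation rate counts phoneme segments per second of
speech (pauses excluded), not syllables. The vowel inventory defining
"all vowels" is the Hungarian SAMPA vowel set by default and is
configurable.

## H2B scale linking

The four HAMD severity categories map onto the matching BDI categories
with linear interpolation inside each closed category:
`h2b = bdi_lo + (hamd − hamd_lo)·(bdi_hi − bdi_lo)/(hamd_hi − hamd_lo)`.
The map is exact at endpoints (0→0, 7→13, 8→14, 13→19, 14→20, 18→28,
19→29, 48→63), monotone, category-preserving, and invertible on category
interiors. Between-category steps (7→13 vs 8→14) are left as-is — each
category is fitted independently, with no smoothing across the one-point
gap. Outputs are real-valued; rounding is presentational only, since a
regression target benefits from continuity. HAMD inputs must be integers
(the instrument is integer-valued). The depression boundary on the BDI
scale is 14 (scores ≥ 14 count as depressed).

## Nested cross-validation

Models are ε-SVR with RBF kernel, trained separately per gender stratum
(strata below 5 subjects are skipped and reported). The outer loop is
leave-one-out (or five stratified folds: subjects are walked in target
order and dealt into folds, seeded). Per outer fold, using training data
only:

1. missing features are imputed with training-fold means and all features
   z-scored with training-fold statistics;
2. **Pearson filter**: the 20 features with the largest |r| against the
   training targets (zero-variance features count as r = 0; ties resolve
   to canonical feature order);
3. **forward selection**: greedily add the candidate minimizing inner
   leave-one-out RMSE of an SVR at fixed cost 1 and gamma 1/#features;
   stop when no addition improves or at 20 features. The first step
   always admits the best single candidate, so the subset is never
   empty. Selection and tuning are deliberately sequential rather than
   joint — a joint search over subsets × 225 grid points would multiply
   the cost without a clear statistical benefit;
4. **grid search**: all 225 (cost, gamma) pairs over powers of two from
   2⁻⁷ to 2⁷, scored by inner leave-one-out RMSE on the selected subset;
   ties resolve to the smallest cost, then the smallest gamma;
5. the final SVR is fit on the full training fold and predicts the
   held-out subject.

ε is fixed at 1.0 score points (only cost and gamma are tuned);
standardization is required in practice for an RBF kernel over features
with heterogeneous units. Predictions are not clipped to [0, 63].
Subjects are processed in `subject_id` order, so results are invariant to
input row order; everything is deterministic given the config seed.
A stability report lists features selected in ≥ 90% of outer folds.

### Inner-loop solver

Nested LOOCV with the full grid evaluates ~3×10⁶ small SVR fits per
cohort. The inner loops therefore use a dedicated SMO solver
(`depspeech._smo`, numba-compiled) for the ε-SVR dual on precomputed
kernels, with two warm-start paths a generic library cannot offer: the
solution at one cost seeds the next cost on the same kernel, and the
full-sample solution seeds every leave-one-out fold. Its stopping rule
and bias convention follow the standard maximal-violating-pair
formulation, and the test suite asserts agreement with scikit-learn's
`SVR` (same dual objective, predictions within tolerance, matching grid
winners). Final per-fold models and anything user-facing use
scikit-learn's `SVR` directly. At the default tolerance (1e−3) the inner
solver makes a 120-subject nested LOOCV run in a few minutes on one CPU.

## Evaluation machinery

Regression metrics are standard; the signed mean error is
prediction − target (positive = overestimation). Classification derives
from the regression output: a subject is called depressed when its
predicted score reaches a comparator threshold, swept over all distinct
predicted values plus ±∞ sentinels, giving an exact step ROC whose
trapezoidal AUC equals the Mann–Whitney concordance (asserted to 1e−10).
Two operating points are reported: maximum accuracy (ties: higher
sensitivity, then lower threshold) and maximum specificity subject to
sensitivity ≥ 90%. The error-difference histogram bins
|pred − BDI| − |pred − H2B| into {|d| < 2 ("nearly identical"), ±[2, 6),
±[6, 13), ±≥ 13}; positive mass means predictions sit closer to H2B.
Comparison tests are two-sided with no multiple-testing correction:
paired/independent t, Fisher r-to-z for two correlations, and Wilcoxon
signed-ranks (exact up to n = 25, normal approximation with tie and
continuity correction beyond). Degenerate inputs (identical pairs,
single-class truth) are flagged rather than silently dropped; identical
paired samples report p = 1 by convention.

The report builder assembles, from two prediction sets (BDI-trained and
H2B-trained): metrics per subject set (I = BDI only, II = both scores,
All) × evaluation target × stratum; the model-vs-questionnaire comparison
on Set II only (the questionnaire "predictor" is the raw BDI score
evaluated against H2B — Set II is where both instruments exist); the
error-difference histogram; and the classification block for both
training variants against H2B truth.

## Synthetic data: what it emulates, what it does not

**Phonations** are source-filter synthesis: an impulse train with
exponential glottal decay through a cascade of second-order resonators.
The base period is quantized to the sample grid, so zero perturbation
yields exactly constant realized periods at any F0; per-cycle period and
amplitude perturbations are i.i.d. Gaussian with SD scaled by
√π/2 so the *expected* local jitter/shimmer equals the requested
percentage — and the realized per-cycle sequences are returned, so
downstream recovery is always measured against exact, not nominal,
ground truth. **Readings** concatenate labelled phonations and silences;
tier boundaries are exact by construction, which makes articulation rate,
pause ratio and transient ratios trivially verifiable.

**Cohorts** draw a latent severity s ∈ [0, 1] per subject — by default a
mixture of a near-zero block (~half the cohort healthy) and a uniform
spread over the depressed range, matching a cohort that is half healthy
with depression severities covered almost evenly. Scores are
BDI = clip(round(63·s + self-report noise)) and
HAMD = clip(round(48·s + clinician noise)); the HAMD subset is exactly
⌊n·fraction⌋ subjects sampled with severity-proportional weights
(0.1 + s), reproducing a depression-skewed clinician-rated subset that
still contains some healthy subjects. When a target BDI–HAMD correlation
is requested, the equal-relative-noise ratio is calibrated by bisection
on the realized (clipped, rounded) scores of the actual HAMD subset —
clipping censors the noise, so the closed-form solution r = 1/(1 + k²)
overshoots by ~0.05 and is only used as a fallback for tiny subsets.
Features load linearly on standardized severity
(`feature_j = effect_j · z(s) + N(0, 1)`), so `effect_j` reads directly
as the per-feature signal-to-noise SD ratio. Defaults mirror the study
population the pipeline targets: 218 subjects, 66% female, HAMD for 20%,
ages ~N(42, 16) clipped to 18–85.

What passing tests on this data **do not** show: the synthesizer has no
prosody, no consonants, no coarticulation, no channel/recording noise,
and the cohort's acoustic-severity link is linear with Gaussian noise.
Recovery and directional results here validate the machinery — the
algorithmic correctness of extraction, selection, tuning and evaluation —
not clinical performance on real speech.

## Problem sizes in the test suite

The acceptance suite exercises: the signal-recovery grid at
F0 ∈ {100, 150, 220} Hz × jitter {0, 1, 2}% × shimmer {0, 3}% on 1.2 s
phonations (tolerances: F0 ±2 Hz, jitter ±0.5 pp, shimmer ±0.75 pp,
F1 ±50 Hz, F2 ±75 Hz); parameter recovery on a 120-subject single-stratum
cohort with five informative features at 3:1 signal-to-noise under the
full nested LOOCV (Pearson ≥ 0.85 against latent severity); and the
directional comparison of training targets on twenty 40-subject
replicates (BDI noise SD 8, HAMD noise SD 2.5, H2B available for all),
requiring the lower-noise target to win in ≥ 15 of 20. The full suite
runs in about six minutes on one CPU.

## Known limitations

* Formant estimation assumes at least two admissible resonances below the
  bandwidth ceiling; breathy or nasal configurations may yield undefined
  frames (handled by missing flags, but reducing effective scope sizes).
* The pulse-marking accuracy degrades for F0 outside 60–400 Hz or for
  phonemes shorter than ~3 cycles; such stretches are excluded rather
  than guessed.
* The H2B map is piecewise-linear with steps between categories; an
  equipercentile or IRT-based linking would be smoother but needs
  item-level data that rating-scale totals do not provide.
* The fivefold outer mode shares all inner machinery but partitions
  subjects once per run; replicate-level variance of fivefold results is
  higher than LOOCV's by construction.
* Wilcoxon on paired per-subject correctness indicators is implemented as
  specified for comparing classification variants; McNemar's test would
  be the textbook choice for paired binary outcomes.
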