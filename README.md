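# depspeech

Speech-based estimation of depression severity, built for researchers in
digital psychiatry and clinical speech analysis who want a tested,
reproducible re-implementation of a complete acoustic-biomarker pipeline:
from annotated read-speech recordings to severity scores, and from severity
scores to the statistics that compare self-reported against
clinician-rated training targets.

## The problem

Depression severity is usually measured either by self-report (Beck
Depression Inventory, BDI, 0–63) or by a clinician (Hamilton Rating Scale
for Depression, HAMD, 0–48). Speech is a promising non-invasive biomarker:
acoustic features of read speech carry enough information to regress a
subject's severity score. But the two instruments sample different
symptoms and correlate only moderately (r ≈ 0.4–0.7), and self-report adds
noise (exaggeration, concealment) to the training targets of any model fit
on BDI labels. This package implements the full machinery needed to study
that question:

* **Acoustic front end** — per 30 ms Hamming frame with 10 ms step:
  intensity, fundamental frequency F0 with a voicing decision, local
  jitter and shimmer from inverse-filtered pulse marks, F1/F2 formant
  frequencies and bandwidths via LPC, and 13 MFCCs. Tracks are aggregated
  by six functionals (mean, SD, and the percentile ranges p99−p1, p95−p5,
  p85−p15, p75−p25) over region scopes (vowel E, vowel O, all vowels,
  whole speech, whole sample, voiced frames), plus articulation rate,
  pause ratio and two transient ratios — a fixed, ordered vector of
  **286 features** per recording (282 from LLD functionals).
* **Scale linking (H2B)** — HAMD is mapped onto the BDI scale by fitting
  the endpoints of the four severity categories (HAMD 0–7 / 8–13 / 14–18 /
  19–48 onto BDI 0–13 / 14–19 / 20–28 / 29–63) with linear interpolation
  within each category. A subject's working score ("H2B") is the
  converted HAMD when a clinician assessment exists, otherwise the BDI.
* **Severity regression** — gender-stratified ε-SVR (RBF kernel) under
  nested leave-one-out cross-validation: per training fold, a Pearson
  top-20 filter, greedy forward selection (max 20 features), and a grid
  search over cost and gamma ∈ {2⁻⁷ … 2⁷} (225 pairs), all scored by inner
  leave-one-out RMSE. The held-out subject never enters imputation,
  standardization, selection or tuning. A stratified fivefold outer mode
  is available for comparison.
* **Evaluation** — RMSE / MAE / signed mean error / Pearson / Spearman per
  subject set and stratum; classification by thresholding the regression
  output with ROC/AUC and two operating points (maximum accuracy;
  maximum specificity at sensitivity ≥ 90%); the signed histogram of
  |error vs BDI| − |error vs H2B|; paired/independent t-tests, Fisher
  r-to-z, and the Wilcoxon signed-ranks test.
* **Synthetic data** — the study cohort this pipeline was designed around
  is not public, so `depspeech.synth` generates (a) formant-synthesized
  phonations and readings whose per-cycle F0/jitter/shimmer ground truth
  is exact by construction, and (b) cohorts with a latent severity that
  drives both rating scales and the acoustic features, including a
  depression-skewed HAMD subset and a configurable BDI–HAMD correlation.

## Worked example

```python
import numpy as np
from depspeech.modeling import ModelConfig, run_nested_cv
from depspeech.synth import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects=50, female_fraction=1.0,
                  effect_vector=(3.0, 3.0, 3.0), n_noise_features=17,
                  bdi_noise_sd=4.0, hamd_subset_fraction=0.0, seed=42)
features, subjects = generate_cohort(spec)
result = run_nested_cv(features, subjects, target="bdi",
                       config=ModelConfig(seed=42))
pred = result.predictions
sev = subjects.sort_values("subject_id")["severity"].to_numpy()
print(np.sqrt(np.mean((pred["y_pred"] - pred["y_true"]) ** 2)))
print(np.corrcoef(pred["y_pred"], sev)[0, 1])
print(result.stability(0.9))
```

prints (exactly, for this seed):

```
6.4171797949357465
0.9614016316021669
  feature  frequency
0    f002        1.0
```

Three of the twenty features carry a severity signal three times their
noise SD; the nested LOOCV recovers the latent severity with r ≈ 0.96
while every prediction comes from a model that never saw its subject, and
the stability report lists the features selected in ≥ 90% of folds
(correlated informative features are interchangeable, so one of
f000–f002 suffices). RMSE ≈ 6.4 score points is measured against the
noisy BDI labels, not the latent truth.

The `examples/` directory holds one short narrative script per
capability: feature extraction from a synthetic reading, H2B conversion,
nested-CV severity modelling, and the full evaluation report.

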