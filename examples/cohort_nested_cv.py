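"""Train gender-stratified SVR severity models under nested LOOCV.

Generates a small synthetic cohort whose acoustic features load linearly
on a latent severity, runs the full nested procedure (Pearson top-k
filter, greedy forward selection, cost/gamma grid search, all tuned by
inner leave-one-out RMSE on each training fold) and reports how well the
completely-held-out predictions recover the latent severity.

Runs in about a minute on one CPU.
"""

import numpy as np

from depspeech.modeling import ModelConfig, run_nested_cv
from depspeech.synth import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects=50, female_fraction=1.0,
                  effect_vector=(3.0, 3.0, 3.0), n_noise_features=17,
                  bdi_noise_sd=4.0, hamd_subset_fraction=0.0, seed=42)
features, subjects = generate_cohort(spec)

config = ModelConfig(seed=42)  # full 15x15 powers-of-two grid, filter 20
result = run_nested_cv(features, subjects, target="bdi", config=config)

pred = result.predictions
sev = subjects.sort_values("subject_id")["severity"].to_numpy()
r_sev = np.corrcoef(pred["y_pred"], sev)[0, 1]
rmse = np.sqrt(np.mean((pred["y_pred"] - pred["y_true"]) ** 2))
print(f"subjects: {len(pred)}; folds: {len(result.fold_results)}")
print(f"RMSE against the (noisy) BDI targets: {rmse:.2f} score points")
print(f"Pearson r against the latent severity: {r_sev:.3f}")
print("features selected in >=90% of folds:")
print(result.stability(0.9).to_string(index=False))

# Every subject is predicted by a model that never saw it during
# imputation, feature selection or tuning; with three informative
# features at signal:noise 3:1, the stability report should recover
# (a subset of) f000-f002 and r against latent severity should be high.
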