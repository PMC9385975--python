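"""Build the full evaluation report from two prediction sets.

Simulates a cohort where both rating scales exist for a 20% subset,
fabricates an "acoustic model" prediction per subject, and assembles the
report: regression metrics per set and stratum for both training
variants, the model-vs-questionnaire comparison on Set II, the
absolute-error-difference histogram, and the classification operating
points with ROC/AUC.
"""

import json

import numpy as np
import pandas as pd

from depspeech.evaluation import build_report
from depspeech.scales import assign_h2b

rng = np.random.default_rng(7)
n = 120
severity = rng.uniform(0, 1, n)
subjects = pd.DataFrame({
    "subject_id": [f"s{i:03d}" for i in range(n)],
    "gender": rng.choice(["male", "female"], n, p=[0.34, 0.66]),
    "bdi": np.clip(np.round(63 * severity + rng.normal(0, 7, n)), 0, 63),
})
hamd_idx = rng.choice(n, n // 5, replace=False)
subjects["hamd"] = np.nan
subjects.loc[hamd_idx, "hamd"] = np.clip(
    np.round(48 * severity[hamd_idx] + rng.normal(0, 3, len(hamd_idx))),
    0, 48)
subjects = assign_h2b(subjects)

# stand-in model outputs: severity plus regression error
pred = pd.DataFrame({
    "subject_id": subjects["subject_id"],
    "gender": subjects["gender"],
    "y_pred": 63 * severity + rng.normal(0, 6, n),
})

report = build_report(pred, pred, subjects)

m_all = report["regression"]["h2b_trained"]["All"]["target_h2b"]["both"]
print(f"All subjects, H2B target: RMSE {m_all['rmse']:.1f}, "
      f"MAE {m_all['mae']:.1f}, Pearson {m_all['pearson']:.2f}")
cmp2 = report["comparison"]["set_II"]
print(f"Set II, model vs questionnaire (against H2B): "
      f"model RMSE {cmp2['acoustic_model']['rmse']:.1f} vs "
      f"questionnaire RMSE {cmp2['bdi_questionnaire']['rmse']:.1f} "
      f"(paired-t on MAE p = {cmp2['paired_t_mae_p']:.3f})")
cls = report["classification"]["h2b_trained"]
op = cls["operating_points"]["max_accuracy"]
print(f"classification vs H2B >= 14: AUC {cls['auc']:.2f}; at max "
      f"accuracy {op['accuracy']:.0%} (sens {op['sensitivity']:.0%}, "
      f"spec {op['specificity']:.0%}, threshold {op['threshold']:.1f})")
print("error-difference histogram (positive bins = closer to H2B):")
print(json.dumps(report["comparison"]["error_difference_histogram"],
                 indent=2))
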