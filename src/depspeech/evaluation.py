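"""Evaluation and comparison machinery for severity predictions.

Regression metrics (RMSE, MAE, signed mean error, Pearson, Spearman),
regression-thresholded classification with ROC/AUC and two operating
points (maximum accuracy; maximum specificity subject to sensitivity
>= 90%), the signed histogram of absolute-error differences between the
BDI and H2B targets, the paired statistical tests used to compare model
variants, and a report builder that assembles all of it per subject set
(I / II / All) and gender stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scales import DEPRESSION_BOUNDARY, depression_label

__all__ = [
    "regression_metrics",
    "classify_by_threshold",
    "roc_auc",
    "operating_points",
    "error_difference_histogram",
    "comparison_tests",
    "build_report",
    "plot_predictions",
    "plot_roc",
    "HISTOGRAM_BIN_EDGES",
]

#: |difference| edges for the error-difference histogram: nearly identical
#: (<2), moderate [2, 6), large [6, 13), very large (>= 13).
HISTOGRAM_BIN_EDGES = (2.0, 6.0, 13.0)


def regression_metrics(predicted, target) -> dict[str, float]:
    """RMSE, MAE, signed mean error (prediction - target), Pearson,
    Spearman (average ranks on ties)."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and target must be equal non-empty")
    err = p - t
    out = {
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "mae": float(np.mean(np.abs(err))),
        "mean_error": float(np.mean(err)),
    }
    if p.size < 2 or np.ptp(p) == 0 or np.ptp(t) == 0:
        out["pearson"] = np.nan
        out["spearman"] = np.nan
    else:
        out["pearson"] = float(stats.pearsonr(p, t).statistic)
        out["spearman"] = float(stats.spearmanr(p, t).statistic)
    return out


def classify_by_threshold(predicted_scores, true_scores,
                          boundary: float = DEPRESSION_BOUNDARY
                          ) -> pd.DataFrame:
    """Sweep classification thresholds over the predicted scores.

    Truth is depressed iff true score >= boundary; a subject is called
    depressed iff its predicted score >= threshold.  Thresholds are the
    distinct predicted values plus -inf/+inf sentinels.  Columns:
    threshold, tp, fp, tn, fn, accuracy, sensitivity, specificity (NaN
    when the truth is single-class).
    """
    p = np.asarray(predicted_scores, dtype=float)
    t = np.asarray(true_scores, dtype=float)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("need equal-length non-empty arrays")
    truth = depression_label(t, boundary)
    thresholds = np.concatenate(([-np.inf], np.unique(p), [np.inf]))
    rows = []
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    for thr in thresholds:
        call = p >= thr
        tp = int((call & truth).sum())
        fp = int((call & ~truth).sum())
        tn = int((~call & ~truth).sum())
        fn = int((~call & truth).sum())
        rows.append({
            "threshold": thr, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": (tp + tn) / len(p),
            "sensitivity": tp / n_pos if n_pos else np.nan,
            "specificity": tn / n_neg if n_neg else np.nan,
        })
    return pd.DataFrame(rows)


def roc_auc(sweep: pd.DataFrame) -> tuple[np.ndarray, float]:
    """ROC points (1 - specificity, sensitivity) and trapezoidal AUC.

    Equals the rank/concordance (Mann-Whitney) statistic.  Degenerate
    single-class input yields NaN AUC.
    """
    if sweep["sensitivity"].isna().any() or sweep["specificity"].isna().any():
        return np.empty((0, 2)), np.nan
    fpr = 1.0 - sweep["specificity"].to_numpy()
    tpr = sweep["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))
    pts = np.column_stack([fpr[order], tpr[order]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def operating_points(sweep: pd.DataFrame,
                     min_sensitivity: float = 0.90) -> dict[str, dict]:
    """The two reported operating points of a threshold sweep.

    ``max_accuracy``: highest accuracy; ties go to higher sensitivity,
    then lower threshold.  ``sensitivity_90``: maximum specificity subject
    to sensitivity >= ``min_sensitivity`` (flagged unattainable if the
    constraint never holds, which requires NaN sensitivities).
    """
    df = sweep.dropna(subset=["sensitivity", "specificity"])
    if df.empty:
        return {"max_accuracy": {"flag": "degenerate"},
                "sensitivity_90": {"flag": "degenerate"}}
    ranked = df.sort_values(
        by=["accuracy", "sensitivity", "threshold"],
        ascending=[False, False, True], kind="stable")
    best = ranked.iloc[0]
    out = {"max_accuracy": {
        "threshold": float(best["threshold"]),
        "accuracy": float(best["accuracy"]),
        "sensitivity": float(best["sensitivity"]),
        "specificity": float(best["specificity"]),
    }}
    ok = df[df["sensitivity"] >= min_sensitivity]
    if ok.empty:
        out["sensitivity_90"] = {"flag": "unattainable"}
    else:
        ranked = ok.sort_values(
            by=["specificity", "accuracy", "threshold"],
            ascending=[False, False, True], kind="stable")
        b = ranked.iloc[0]
        out["sensitivity_90"] = {
            "threshold": float(b["threshold"]),
            "accuracy": float(b["accuracy"]),
            "sensitivity": float(b["sensitivity"]),
            "specificity": float(b["specificity"]),
        }
    return out


def error_difference_histogram(pred, bdi, h2b) -> dict[str, float]:
    """Signed histogram of |pred - bdi| - |pred - h2b| per subject.

    Positive differences mean the prediction sits closer to H2B, negative
    closer to BDI.  Bins: near zero (|d| < 2), then +-[2, 6), +-[6, 13),
    +-[13, inf); the fractions sum to 1.
    """
    p = np.asarray(pred, dtype=float)
    b = np.asarray(bdi, dtype=float)
    h = np.asarray(h2b, dtype=float)
    if not (p.shape == b.shape == h.shape) or p.size == 0:
        raise ValueError("pred, bdi, h2b must be aligned and non-empty")
    d = np.abs(p - b) - np.abs(p - h)
    e1, e2, e3 = HISTOGRAM_BIN_EDGES
    n = d.size
    bins = {
        "bdi_ge13": np.sum(d <= -e3),
        "bdi_6_13": np.sum((d > -e3) & (d <= -e2)),
        "bdi_2_6": np.sum((d > -e2) & (d <= -e1)),
        "near_zero": np.sum(np.abs(d) < e1),
        "h2b_2_6": np.sum((d >= e1) & (d < e2)),
        "h2b_6_13": np.sum((d >= e2) & (d < e3)),
        "h2b_ge13": np.sum(d >= e3),
    }
    return {k: float(v) / n for k, v in bins.items()}


def _fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> float:
    if min(n1, n2) < 4:
        raise ValueError("Fisher r-to-z needs n >= 4 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def comparison_tests(a, b, kind: str, *, n_a: int | None = None,
                     n_b: int | None = None) -> float:
    """Two-sided p-value of the requested comparison.

    kinds: ``paired_t`` and ``wilcoxon_signed_ranks`` take paired samples
    (identical pairs have no variance: p = 1 by convention);
    ``independent_t`` takes two independent samples; ``fisher_r_to_z``
    takes two correlation coefficients with their sample sizes ``n_a``,
    ``n_b``.  The Wilcoxon test is exact up to n = 25 and uses the normal
    approximation with tie correction beyond.
    """
    if kind == "fisher_r_to_z":
        if n_a is None or n_b is None:
            raise ValueError("fisher_r_to_z needs n_a and n_b")
        return _fisher_r_to_z(float(a), n_a, float(b), n_b)
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if kind == "paired_t":
        if x.shape != y.shape or x.size < 2:
            raise ValueError("paired t-test needs paired n >= 2")
        if np.ptp(x - y) == 0:
            return 1.0
        return float(stats.ttest_rel(x, y).pvalue)
    if kind == "independent_t":
        if min(x.size, y.size) < 2:
            raise ValueError("independent t-test needs n >= 2 per group")
        return float(stats.ttest_ind(x, y).pvalue)
    if kind == "wilcoxon_signed_ranks":
        if x.shape != y.shape or x.size < 2:
            raise ValueError("Wilcoxon needs paired n >= 2")
        d = x - y
        if np.all(d == 0):
            return 1.0
        method = "exact" if np.count_nonzero(d) <= 25 else "approx"
        return float(stats.wilcoxon(x, y, method=method,
                                    correction=(method == "approx")).pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def plot_predictions(predicted, target, path,
                     boundary: float = DEPRESSION_BOUNDARY,
                     target_name: str = "H2B") -> None:
    """Scatter of predicted vs original scores with the x = y line and the
    dashed depression boundary on both axes (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t, p, s=14, alpha=0.7)
    hi = max(p.max(), t.max(), boundary) * 1.05
    ax.plot([0, hi], [0, hi], "k-", lw=0.8, label="x = y")
    ax.axvline(boundary, ls="--", c="gray", lw=0.8)
    ax.axhline(boundary, ls="--", c="gray", lw=0.8,
               label=f"{target_name} = {boundary:g}")
    ax.set_xlabel(f"original {target_name} score")
    ax.set_ylabel("predicted score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(roc_points, auc: float, path) -> None:
    """ROC curve with its AUC in the legend (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.asarray(roc_points, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts[:, 0], pts[:, 1], "-", label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Report assembly

def _group_metrics(df: pd.DataFrame, target_col: str) -> dict:
    out = {}
    for label, sub in (("both", df),
                       ("male", df[df["gender"] == "male"]),
                       ("female", df[df["gender"] == "female"])):
        if len(sub):
            out[label] = regression_metrics(sub["y_pred"], sub[target_col])
        else:
            out[label] = {"flag": "empty stratum"}
    return out


def build_report(pred_bdi: pd.DataFrame, pred_h2b: pd.DataFrame,
                 subjects: pd.DataFrame,
                 boundary: float = DEPRESSION_BOUNDARY) -> dict:
    """Assemble the full evaluation report from two prediction sets.

    ``pred_bdi`` / ``pred_h2b`` are prediction tables (subject_id, gender,
    y_pred) from models trained on the BDI and H2B targets; ``subjects``
    carries bdi, h2b and set labels.  The report contains: regression
    metrics per set x evaluation target x stratum for both training
    variants; the model-vs-questionnaire comparison on Set II (the
    questionnaire "predictor" is the raw BDI score evaluated against H2B);
    the error-difference histogram on Set II; and the classification sweep
    (ROC, AUC, both operating points) for both training variants against
    H2B truth.
    """
    need = {"subject_id", "bdi", "h2b", "set", "gender"}
    if not need <= set(subjects.columns):
        raise ValueError(f"subjects table needs columns {sorted(need)}")
    report: dict = {"regression": {}, "classification": {},
                    "comparison": {}, "flags": []}

    merged = {}
    for name, preds in (("bdi_trained", pred_bdi), ("h2b_trained", pred_h2b)):
        m = subjects.merge(preds[["subject_id", "y_pred"]], on="subject_id",
                           validate="1:1")
        merged[name] = m
        per_set: dict = {}
        for set_name, sub in (("I", m[m["set"] == "I"]),
                              ("II", m[m["set"] == "II"]), ("All", m)):
            if not len(sub):
                per_set[set_name] = {"flag": "empty set"}
                report["flags"].append(f"{name}: set {set_name} empty")
                continue
            per_set[set_name] = {
                "target_bdi": _group_metrics(sub, "bdi"),
                "target_h2b": _group_metrics(sub, "h2b"),
            }
        report["regression"][name] = per_set

    # model vs questionnaire on Set II (both scores exist there only)
    m2 = merged["h2b_trained"]
    set2 = m2[m2["set"] == "II"]
    if len(set2) >= 2:
        report["comparison"]["set_II"] = {
            "bdi_questionnaire": regression_metrics(set2["bdi"], set2["h2b"]),
            "acoustic_model": regression_metrics(set2["y_pred"], set2["h2b"]),
            "paired_t_mae_p": comparison_tests(
                np.abs(set2["bdi"] - set2["h2b"]),
                np.abs(set2["y_pred"] - set2["h2b"]), "paired_t"),
        }
    else:
        report["flags"].append("Set II too small for comparison")

    b2 = merged["bdi_trained"]
    set2b = b2[b2["set"] == "II"]
    if len(set2b):
        report["comparison"]["error_difference_histogram"] = \
            error_difference_histogram(set2b["y_pred"], set2b["bdi"],
                                       set2b["h2b"])

    for name, m in merged.items():
        sweep = classify_by_threshold(m["y_pred"], m["h2b"], boundary)
        pts, auc = roc_auc(sweep)
        report["classification"][name] = {
            "auc": auc,
            "roc_points": pts.tolist(),
            "operating_points": operating_points(sweep),
        }
        if np.isnan(auc):
            report["flags"].append(f"{name}: single-class truth, AUC undefined")
    return report
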