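"""Gender-stratified SVR severity regression under nested cross-validation.

Outer loop: leave-one-out (or stratified fivefold) over the subjects of
one gender stratum.  Inside each training fold, and using inner
leave-one-out RMSE only on that fold:

1. Pearson filter — keep the 20 features most correlated (|r|) with the
   training targets;
2. fast forward selection — greedily add the candidate that lowers inner
   LOOCV RMSE of an RBF-kernel SVR (fixed cost 1, gamma 1/#features),
   stop at no improvement or 20 features;
3. grid search — cost and gamma over powers of two from 2^-7 to 2^7
   (15 x 15 = 225 pairs) on the selected subset;

then an SVR with the winning subset and pair is fit on the whole training
fold and predicts the held-out subject.  The held-out subject never enters
imputation, standardization, filtering, selection or tuning.

Implementation note: inner LOOCV evaluates thousands of small SVR fits per
outer fold, so kernels are precomputed — per-feature squared-distance
matrices are built once per outer fold and summed incrementally as the
forward selection grows its subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from ._smo import loocv_sq_errors

__all__ = [
    "ModelConfig",
    "FoldResult",
    "NestedCVResult",
    "pearson_filter",
    "forward_select",
    "grid_search_svr",
    "run_nested_cv",
    "feature_stability",
]

_GRID_EXPONENTS = tuple(range(-7, 8))


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the nested-CV procedure (defaults are the
    published protocol; shrink the grids only for scaled-down studies)."""

    cost_grid: tuple[float, ...] = tuple(2.0 ** e for e in _GRID_EXPONENTS)
    gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in _GRID_EXPONENTS)
    filter_k: int = 20
    forward_max: int = 20
    cv_mode: str = "nested_loocv"  # or "nested_fivefold"
    inner_criterion: str = "rmse"
    epsilon: float = 1.0           # SVR tube width, score points
    svm_tol: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.filter_k < 1 or self.forward_max < 1:
            raise ValueError("filter_k and forward_max must be >= 1")
        if self.cv_mode not in ("nested_loocv", "nested_fivefold"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        if self.inner_criterion != "rmse":
            raise ValueError("only the RMSE inner criterion is supported")


@dataclass
class FoldResult:
    """Per-outer-fold record: what was selected and what was predicted."""

    test_subject_ids: tuple[str, ...]
    predicted: np.ndarray
    selected_features: tuple[str, ...]
    chosen_cost: float
    chosen_gamma: float


@dataclass
class NestedCVResult:
    """Predictions (one row per subject) plus per-fold selection logs."""

    predictions: pd.DataFrame   # subject_id, gender, target, y_true, y_pred
    fold_results: list[FoldResult]
    skipped_strata: dict[str, int] = field(default_factory=dict)

    def stability(self, threshold: float = 0.9) -> pd.DataFrame:
        return feature_stability(self.fold_results, threshold)


def pearson_filter(train_features: pd.DataFrame, train_targets: np.ndarray,
                   k: int = 20) -> list[str]:
    """Top-k feature names by |Pearson r| with the target.

    Zero-variance features count as r = 0; exact ties resolve to the
    earlier column (canonical feature order).
    """
    X = train_features.to_numpy(dtype=float)
    y = np.asarray(train_targets, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 training samples")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    order = np.argsort(-np.abs(r), kind="stable")  # stable => canonical ties
    return [train_features.columns[i] for i in order[:k]]


def _loocv_rmse_kernel(K: np.ndarray, y: np.ndarray, C: float,
                       epsilon: float, tol: float,
                       beta_init: np.ndarray | None = None
                       ) -> tuple[float, np.ndarray]:
    """Leave-one-out RMSE of an SVR on a precomputed kernel matrix.

    Solved with the package's warm-startable SMO (see ``_smo``); returns
    (rmse, full-sample dual coefficients) so that successive cost values
    on the same kernel can chain warm starts.
    """
    sq, beta = loocv_sq_errors(K, y, C, epsilon, tol, beta_init=beta_init)
    return float(np.sqrt(sq.mean())), beta


def forward_select(train_features: pd.DataFrame, train_targets: np.ndarray,
                   candidates: Sequence[str], config: ModelConfig
                   ) -> list[str]:
    """Greedy forward selection by inner-LOOCV RMSE of a fixed-parameter SVR.

    SVR is evaluated at cost 1 and gamma 1/#features of the candidate
    subset.  The first step always admits the best single candidate (the
    subset is never empty); later steps require a strict RMSE improvement.
    RMSE ties resolve to the candidate earliest in canonical column order.
    """
    config.validate()
    y = np.asarray(train_targets, dtype=float)
    canon = {name: i for i, name in enumerate(train_features.columns)}
    cand = list(candidates)
    # per-feature squared-distance matrices, summed as the subset grows
    dist = {c: _sq_dist(train_features[c].to_numpy(dtype=float))
            for c in cand}
    selected: list[str] = []
    d_sel = np.zeros_like(next(iter(dist.values())))
    best_rmse = np.inf
    while cand and len(selected) < config.forward_max:
        step_best: tuple[float, int, str] | None = None
        gamma = 1.0 / (len(selected) + 1)
        for c in cand:
            K = np.exp(-gamma * (d_sel + dist[c]))
            rmse, _ = _loocv_rmse_kernel(K, y, 1.0, config.epsilon,
                                         config.svm_tol)
            key = (rmse, canon[c])
            if step_best is None or key < step_best[:2]:
                step_best = (rmse, canon[c], c)
        rmse, _, name = step_best
        if selected and rmse >= best_rmse:
            break
        best_rmse = rmse
        selected.append(name)
        d_sel = d_sel + dist[name]
        cand.remove(name)
    return selected


def _sq_dist(col: np.ndarray) -> np.ndarray:
    d = col[:, None] - col[None, :]
    return d * d


def grid_search_svr(train_features: pd.DataFrame, train_targets: np.ndarray,
                    config: ModelConfig) -> tuple[float, float]:
    """Best (cost, gamma) by inner-LOOCV RMSE over the powers-of-two grid.

    Ties resolve to the smallest cost, then the smallest gamma.  Degenerate
    (all-equal) targets warn and return the grid minimum.
    """
    config.validate()
    y = np.asarray(train_targets, dtype=float)
    if train_features.shape[1] == 0:
        raise ValueError("empty feature subset")
    if np.ptp(y) == 0:
        warnings.warn("degenerate targets (all equal); returning grid "
                      "minimum", RuntimeWarning, stacklevel=2)
        return min(config.cost_grid), min(config.gamma_grid)
    X = train_features.to_numpy(dtype=float)
    D = sum(_sq_dist(X[:, j]) for j in range(X.shape[1]))
    best: tuple[float, float, float] | None = None  # rmse, cost, gamma
    for gamma in sorted(config.gamma_grid):
        K = np.exp(-gamma * D)
        beta = None  # warm-start chain along increasing cost
        for cost in sorted(config.cost_grid):
            rmse, beta = _loocv_rmse_kernel(K, y, cost, config.epsilon,
                                            config.svm_tol, beta_init=beta)
            if best is None or rmse < best[0] - 1e-12 or (
                    abs(rmse - best[0]) <= 1e-12
                    and (cost, gamma) < (best[1], best[2])):
                best = (rmse, cost, gamma)
    return best[1], best[2]


def _outer_folds(y: np.ndarray, mode: str, seed: int) -> list[np.ndarray]:
    n = len(y)
    if mode == "nested_loocv":
        return [np.array([i]) for i in range(n)]
    # stratified fivefold: walk subjects in target order, deal each
    # consecutive block of five into the five folds in seeded order
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    fold_of = np.empty(n, dtype=int)
    for start in range(0, n, 5):
        block = order[start:start + 5]
        deal = rng.permutation(5)[:len(block)]
        fold_of[block] = deal
    return [np.flatnonzero(fold_of == f) for f in range(5)]


def run_nested_cv(features: pd.DataFrame, subjects: pd.DataFrame,
                  target: str = "bdi",
                  config: ModelConfig = ModelConfig(),
                  min_stratum: int = 5) -> NestedCVResult:
    """Run the full nested procedure, one model family per gender stratum.

    ``features`` holds subject_id plus feature columns; ``subjects`` holds
    subject_id, gender and the target column.  Subjects are processed in
    subject_id order, so the per-subject predictions are invariant to the
    input row order.  Strata smaller than ``min_stratum`` are skipped and
    reported.
    """
    config.validate()
    merged = subjects.merge(features, on="subject_id", validate="1:1")
    merged = merged.sort_values("subject_id").reset_index(drop=True)
    feat_cols = [c for c in features.columns if c != "subject_id"]

    rows = []
    folds_out: list[FoldResult] = []
    skipped: dict[str, int] = {}
    for gender, grp in merged.groupby("gender", sort=True):
        n = len(grp)
        if n < min_stratum:
            skipped[str(gender)] = n
            continue
        X_all = grp[feat_cols].to_numpy(dtype=float)
        y_all = grp[target].to_numpy(dtype=float)
        ids = grp["subject_id"].to_numpy()
        for test_idx in _outer_folds(y_all, config.cv_mode, config.seed):
            tr = np.setdiff1d(np.arange(n), test_idx)
            X_tr, y_tr = X_all[tr].copy(), y_all[tr]
            # impute + standardize with training-fold statistics only
            col_mean = np.nanmean(X_tr, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            nan_r, nan_c = np.where(~np.isfinite(X_tr))
            X_tr[nan_r, nan_c] = col_mean[nan_c]
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            X_tr = (X_tr - mu) / sd
            X_te = X_all[test_idx].copy()
            nan_r, nan_c = np.where(~np.isfinite(X_te))
            X_te[nan_r, nan_c] = col_mean[nan_c]
            X_te = (X_te - mu) / sd

            df_tr = pd.DataFrame(X_tr, columns=feat_cols)
            if len(y_tr) >= 3:
                cands = pearson_filter(df_tr, y_tr, config.filter_k)
            else:  # tiny toy folds: correlation filter is undefined
                cands = feat_cols[:config.filter_k]
            subset = forward_select(df_tr, y_tr, cands, config)
            cost, gamma = grid_search_svr(df_tr[subset], y_tr, config)
            model = SVR(kernel="rbf", C=cost, gamma=gamma,
                        epsilon=config.epsilon, tol=config.svm_tol)
            cols_idx = [feat_cols.index(s) for s in subset]
            model.fit(X_tr[:, cols_idx], y_tr)
            pred = model.predict(X_te[:, cols_idx])
            folds_out.append(FoldResult(
                test_subject_ids=tuple(ids[test_idx]),
                predicted=pred, selected_features=tuple(subset),
                chosen_cost=cost, chosen_gamma=gamma))
            for j, ti in enumerate(test_idx):
                rows.append((ids[ti], gender, target, y_all[ti], pred[j]))
    predictions = pd.DataFrame(
        rows, columns=["subject_id", "gender", "target", "y_true", "y_pred"]
    ).sort_values("subject_id").reset_index(drop=True)
    return NestedCVResult(predictions=predictions, fold_results=folds_out,
                          skipped_strata=skipped)


def feature_stability(fold_results: Sequence[FoldResult],
                      threshold: float = 0.9) -> pd.DataFrame:
    """Features selected in at least ``threshold`` of all folds.

    Returns a frame (feature, frequency) sorted by descending frequency;
    empty when there are no folds.
    """
    if not fold_results:
        return pd.DataFrame(columns=["feature", "frequency"])
    counts: dict[str, int] = {}
    for fr in fold_results:
        for name in fr.selected_features:
            counts[name] = counts.get(name, 0) + 1
    n = len(fold_results)
    rows = [(name, c / n) for name, c in counts.items()
            if c / n >= threshold]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["feature", "frequency"])
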