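"""Nested-CV machinery: filtering, forward selection, grid search, fold
structure, leakage protection and determinism."""

import numpy as np
import pandas as pd
import pytest

from depspeech.modeling import (ModelConfig, feature_stability,
                                forward_select, grid_search_svr,
                                pearson_filter, run_nested_cv)
from depspeech.synth import CohortSpec, generate_cohort

SMALL = ModelConfig(cost_grid=(0.25, 1.0, 4.0), gamma_grid=(0.25, 1.0, 4.0),
                    filter_k=6, forward_max=4, seed=0)


def toy_frame(rng, n=30, p=6):
    X = rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=[f"f{j:03d}" for j in range(p)])


class TestPearsonFilter:
    def test_target_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        df = toy_frame(rng)
        y = df["f003"].to_numpy()
        assert pearson_filter(df, y, k=3)[0] == "f003"

    def test_k_larger_than_feature_count(self):
        rng = np.random.default_rng(1)
        df = toy_frame(rng, p=4)
        y = rng.normal(size=30)
        assert len(pearson_filter(df, y, k=10)) == 4

    def test_zero_variance_feature_ranks_last(self):
        rng = np.random.default_rng(2)
        df = toy_frame(rng, p=3)
        df["f000"] = 5.0
        y = df["f002"].to_numpy() + 0.1 * rng.normal(size=30)
        assert pearson_filter(df, y, k=3)[-1] == "f000"

    def test_signal_features_dominate_noise(self):
        spec = CohortSpec(n_subjects=200, effect_vector=(3.0, 3.0, 3.0),
                          n_noise_features=30, bdi_noise_sd=3.0,
                          hamd_subset_fraction=0.0, seed=4)
        feats, subs = generate_cohort(spec)
        top = pearson_filter(feats.drop(columns="subject_id"),
                             subs["bdi"].to_numpy(), k=3)
        assert set(top) == {"f000", "f001", "f002"}

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            pearson_filter(toy_frame(rng, n=2), np.zeros(2))


class TestForwardSelection:
    def test_single_predictive_feature_selected_alone(self):
        rng = np.random.default_rng(5)
        df = toy_frame(rng, n=40)
        y = 10.0 * df["f002"].to_numpy()
        subset = forward_select(df, y, list(df.columns), SMALL)
        assert subset[0] == "f002" and len(subset) <= 2

    def test_exact_duplicate_selected_at_most_once(self):
        rng = np.random.default_rng(6)
        df = toy_frame(rng, n=40, p=3)
        df["f003"] = df["f000"]  # exact copy
        y = 5.0 * df["f000"].to_numpy() + rng.normal(size=40)
        subset = forward_select(df, y, list(df.columns), SMALL)
        assert not ({"f000", "f003"} <= set(subset))

    def test_never_returns_empty(self):
        rng = np.random.default_rng(7)
        df = toy_frame(rng, n=20, p=3)
        y = rng.normal(size=20)  # pure noise: nothing helps
        subset = forward_select(df, y, list(df.columns), SMALL)
        assert len(subset) >= 1

    def test_matches_independent_greedy_oracle(self):
        # brute-force re-implementation of the greedy path, evaluated with
        # sklearn SVR leave-one-out (independent of the package's solver)
        from sklearn.svm import SVR

        rng = np.random.default_rng(8)
        df = toy_frame(rng, n=24, p=5)
        y = (4.0 * df["f001"] + 2.0 * df["f003"]
             + 0.3 * rng.normal(size=24)).to_numpy()
        cfg = ModelConfig(filter_k=5, forward_max=3, seed=0)

        def loocv_rmse(cols):
            X = df[cols].to_numpy()
            err = []
            for i in range(len(y)):
                tr = np.arange(len(y)) != i
                m = SVR(kernel="rbf", C=1.0, gamma=1.0 / len(cols),
                        epsilon=1.0, tol=1e-3).fit(X[tr], y[tr])
                err.append(m.predict(X[i][None, :])[0] - y[i])
            return np.sqrt(np.mean(np.square(err)))

        remaining = list(df.columns)
        selected, best = [], np.inf
        while remaining and len(selected) < cfg.forward_max:
            scored = [(loocv_rmse(selected + [c]), c) for c in remaining]
            rmse, name = min(scored)
            if selected and rmse >= best:
                break
            best = rmse
            selected.append(name)
            remaining.remove(name)

        assert forward_select(df, y, list(df.columns), cfg) == selected


class TestGridSearch:
    def test_grid_has_225_candidates(self):
        cfg = ModelConfig()
        assert len(cfg.cost_grid) * len(cfg.gamma_grid) == 225
        assert min(cfg.cost_grid) == 2.0 ** -7
        assert max(cfg.gamma_grid) == 2.0 ** 7

    def test_matches_brute_force_grid_oracle(self):
        from sklearn.svm import SVR

        rng = np.random.default_rng(9)
        df = toy_frame(rng, n=20, p=2)
        y = (3.0 * df["f000"] - 2.0 * df["f001"]).to_numpy()
        cfg = ModelConfig(cost_grid=(0.5, 2.0, 8.0),
                          gamma_grid=(0.125, 0.5, 2.0), seed=0)

        best = None
        for cost in cfg.cost_grid:
            for gamma in cfg.gamma_grid:
                err = []
                X = df.to_numpy()
                for i in range(len(y)):
                    tr = np.arange(len(y)) != i
                    m = SVR(kernel="rbf", C=cost, gamma=gamma, epsilon=1.0,
                            tol=1e-3).fit(X[tr], y[tr])
                    err.append(m.predict(X[i][None, :])[0] - y[i])
                rmse = np.sqrt(np.mean(np.square(err)))
                if best is None or rmse < best[0] - 1e-9:
                    best = (rmse, cost, gamma)
        assert grid_search_svr(df, y, cfg) == (best[1], best[2])

    def test_degenerate_targets_warn(self):
        rng = np.random.default_rng(10)
        df = toy_frame(rng, n=10, p=2)
        with pytest.warns(RuntimeWarning):
            pair = grid_search_svr(df, np.full(10, 5.0), SMALL)
        assert pair == (min(SMALL.cost_grid), min(SMALL.gamma_grid))


def _toy_dataset(n=12, seed=0, gender="female"):
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame({
        "subject_id": [f"s{i:02d}" for i in range(n)],
        "f000": rng.normal(size=n),
        "f001": rng.normal(size=n),
    })
    subjects = pd.DataFrame({
        "subject_id": feats["subject_id"],
        "gender": [gender] * n,
        "bdi": np.clip(np.round(30 + 10 * feats["f000"]
                                + 2 * rng.normal(size=n)), 0, 63),
    })
    return feats, subjects


class TestNestedCV:
    def test_loocv_fold_structure(self):
        feats, subjects = _toy_dataset(n=6)
        res = run_nested_cv(feats, subjects, target="bdi", config=SMALL,
                            min_stratum=3)
        assert len(res.fold_results) == 6
        assert len(res.predictions) == 6
        held_out = {fr.test_subject_ids[0] for fr in res.fold_results}
        assert held_out == set(feats["subject_id"])

    def test_three_subject_stratum_with_relaxed_minimum(self):
        feats, subjects = _toy_dataset(n=3)
        res = run_nested_cv(feats, subjects, target="bdi", config=SMALL,
                            min_stratum=3)
        assert len(res.fold_results) == 3

    def test_small_stratum_skipped_and_reported(self):
        feats, subjects = _toy_dataset(n=4)
        res = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        assert res.skipped_strata == {"female": 4}
        assert len(res.predictions) == 0

    def test_corrupting_held_out_target_changes_nothing(self):
        feats, subjects = _toy_dataset(n=10, seed=1)
        res1 = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        corrupted = subjects.copy()
        sid = corrupted["subject_id"].iloc[3]
        corrupted.loc[corrupted["subject_id"] == sid, "bdi"] = 63.0
        res2 = run_nested_cv(feats, corrupted, target="bdi", config=SMALL)
        p1 = res1.predictions.set_index("subject_id")["y_pred"]
        p2 = res2.predictions.set_index("subject_id")["y_pred"]
        assert p1[sid] == p2[sid]

    def test_row_order_permutation_invariance(self):
        feats, subjects = _toy_dataset(n=10, seed=2)
        res1 = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        perm = np.random.default_rng(0).permutation(10)
        res2 = run_nested_cv(feats.iloc[perm].reset_index(drop=True),
                             subjects.iloc[perm].reset_index(drop=True),
                             target="bdi", config=SMALL)
        pd.testing.assert_frame_equal(res1.predictions, res2.predictions)

    def test_determinism_across_runs(self):
        feats, subjects = _toy_dataset(n=10, seed=3)
        res1 = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        res2 = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        pd.testing.assert_frame_equal(res1.predictions, res2.predictions)

    def test_genders_modelled_separately(self):
        f1, s1 = _toy_dataset(n=8, seed=4, gender="female")
        f2, s2 = _toy_dataset(n=8, seed=5, gender="male")
        f2 = f2.assign(subject_id=[f"m{i:02d}" for i in range(8)])
        s2 = s2.assign(subject_id=f2["subject_id"])
        both_f = pd.concat([f1, f2], ignore_index=True)
        both_s = pd.concat([s1, s2], ignore_index=True)
        res_joint = run_nested_cv(both_f, both_s, target="bdi", config=SMALL)
        res_female = run_nested_cv(f1, s1, target="bdi", config=SMALL)
        joint_f = res_joint.predictions.query("gender == 'female'")
        merged = joint_f.merge(res_female.predictions, on="subject_id",
                               suffixes=("_joint", "_alone"))
        np.testing.assert_allclose(merged["y_pred_joint"],
                                   merged["y_pred_alone"])

    def test_fivefold_partition(self):
        feats, subjects = _toy_dataset(n=20, seed=6)
        cfg = ModelConfig(cost_grid=(1.0,), gamma_grid=(0.5,), filter_k=2,
                          forward_max=2, cv_mode="nested_fivefold", seed=1)
        res = run_nested_cv(feats, subjects, target="bdi", config=cfg)
        assert len(res.fold_results) == 5
        sizes = sorted(len(fr.test_subject_ids) for fr in res.fold_results)
        assert sizes == [4, 4, 4, 4, 4]
        assert len(res.predictions) == 20

    def test_missing_features_imputed_from_training_fold(self):
        feats, subjects = _toy_dataset(n=10, seed=7)
        feats.loc[2, "f001"] = np.nan
        res = run_nested_cv(feats, subjects, target="bdi", config=SMALL)
        assert np.isfinite(res.predictions["y_pred"]).all()


class TestStability:
    def make_folds(self, n, name_lists):
        from depspeech.modeling import FoldResult
        return [FoldResult(test_subject_ids=(f"s{i}",),
                           predicted=np.array([0.0]),
                           selected_features=tuple(names),
                           chosen_cost=1.0, chosen_gamma=1.0)
                for i, names in enumerate(name_lists)]

    def test_always_selected_reported_at_one(self):
        folds = self.make_folds(10, [["a", "b"]] * 10)
        out = feature_stability(folds, threshold=0.9)
        assert set(out["feature"]) == {"a", "b"}
        assert (out["frequency"] == 1.0).all()

    def test_89_percent_excluded_at_90_threshold(self):
        lists = [["a"]] * 89 + [["b"]] * 11
        out = feature_stability(self.make_folds(100, lists), threshold=0.9)
        assert out.empty

    def test_no_folds_empty_report(self):
        assert feature_stability([], threshold=0.9).empty
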