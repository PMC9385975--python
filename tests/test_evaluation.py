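"""Evaluation machinery against brute-force oracles: metrics, threshold
sweeps, ROC/AUC identities, operating points, histograms, paired tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depspeech.evaluation import (classify_by_threshold, comparison_tests,
                                  error_difference_histogram, build_report,
                                  operating_points, regression_metrics,
                                  roc_auc)


def brute_force_metrics(p, t):
    n = len(p)
    err = [pi - ti for pi, ti in zip(p, t)]
    rmse = (sum(e * e for e in err) / n) ** 0.5
    mae = sum(abs(e) for e in err) / n
    me = sum(err) / n
    mp, mt = sum(p) / n, sum(t) / n
    cov = sum((pi - mp) * (ti - mt) for pi, ti in zip(p, t))
    sp = sum((pi - mp) ** 2 for pi in p) ** 0.5
    st_ = sum((ti - mt) ** 2 for ti in t) ** 0.5
    pear = cov / (sp * st_)

    def ranks(x):
        order = sorted(range(n), key=lambda i: x[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and x[order[j + 1]] == x[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k2 in range(i, j + 1):
                r[order[k2]] = avg
            i = j + 1
        return r

    spear = brute_pearson(ranks(list(p)), ranks(list(t)))
    return rmse, mae, me, pear, spear


def brute_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    sa = sum((x - ma) ** 2 for x in a) ** 0.5
    sb = sum((y - mb) ** 2 for y in b) ** 0.5
    return cov / (sa * sb)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["rmse"] == 0 and m["mae"] == 0
        assert m["pearson"] == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks_spearman(self):
        m = regression_metrics([1.0, 2.0, 3.0, 4.0], [8.0, 6.0, 4.0, 2.0])
        assert m["spearman"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        p = rng.normal(size=n) * 10
        t = rng.normal(size=n) * 10
        m = regression_metrics(p, t)
        rmse, mae, me, pear, spear = brute_force_metrics(p, t)
        assert m["rmse"] == pytest.approx(rmse, abs=1e-10)
        assert m["mae"] == pytest.approx(mae, abs=1e-10)
        assert m["mean_error"] == pytest.approx(me, abs=1e-10)
        assert m["pearson"] == pytest.approx(pear, abs=1e-10)
        assert m["spearman"] == pytest.approx(spear, abs=1e-10)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p, t = rng.normal(size=30), rng.normal(size=30)
            m = regression_metrics(p, t)
            assert m["rmse"] >= m["mae"] >= 0

    def test_mean_error_sign_convention(self):
        m = regression_metrics([5.0, 5.0], [2.0, 2.0])
        assert m["mean_error"] == pytest.approx(3.0)  # prediction - target

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0, 2.0])


class TestThresholdSweep:
    def test_perfect_separation_reaches_accuracy_one(self):
        sweep = classify_by_threshold([1, 2, 3, 20, 25, 30],
                                      [0, 5, 10, 20, 30, 40])
        assert sweep["accuracy"].max() == 1.0

    def test_extreme_thresholds(self):
        sweep = classify_by_threshold([5.0, 20.0], [5.0, 20.0])
        low = sweep.iloc[0]   # -inf: everyone called depressed
        high = sweep.iloc[-1]  # +inf: nobody called depressed
        assert low["sensitivity"] == 1.0 and low["specificity"] == 0.0
        assert high["sensitivity"] == 0.0 and high["specificity"] == 1.0

    def test_confusion_counts_match_hand_enumeration(self):
        pred = [10.0, 16.0, 12.0, 20.0, 8.0, 30.0]
        true = [5.0, 20.0, 15.0, 10.0, 3.0, 40.0]  # depressed: t >= 14
        sweep = classify_by_threshold(pred, true)
        row = sweep[sweep["threshold"] == 16.0].iloc[0]
        # called depressed: pred >= 16 -> subjects 1, 3, 5
        assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (2, 1, 2, 1)

    def test_single_class_truth_flagged(self):
        sweep = classify_by_threshold([1.0, 2.0], [20.0, 30.0])
        assert sweep["specificity"].isna().all()


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        sweep = classify_by_threshold([1, 2, 20, 30], [0, 5, 20, 40])
        _, auc = roc_auc(sweep)
        assert auc == pytest.approx(1.0)

    def test_random_predictions_auc_half(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(20, 10, size=4000)
        true = rng.choice([5.0, 25.0], size=4000)
        _, auc = roc_auc(classify_by_threshold(pred, true))
        assert auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        pred = rng.normal(15, 8, size=n)
        true = rng.uniform(0, 40, size=n)
        if not ((true >= 14).any() and (true < 14).any()):
            pytest.skip("degenerate draw")
        sweep = classify_by_threshold(pred, true)
        _, auc = roc_auc(sweep)
        pos, neg = pred[true >= 14], pred[true < 14]
        u = sum((pos[:, None] > neg[None, :]).sum()
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
                for _ in [0])
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-10)

    def test_degenerate_input_flagged(self):
        sweep = classify_by_threshold([1.0, 2.0], [20.0, 30.0])
        pts, auc = roc_auc(sweep)
        assert np.isnan(auc) and pts.size == 0


class TestOperatingPoints:
    def test_separable_toy_perfect_point(self):
        sweep = classify_by_threshold([1, 2, 20, 30], [0, 5, 20, 40])
        ops = operating_points(sweep)
        assert ops["max_accuracy"]["sensitivity"] == 1.0
        assert ops["max_accuracy"]["specificity"] == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        pred = rng.normal(15, 8, size=10)
        true = rng.uniform(0, 40, size=10)
        sweep = classify_by_threshold(pred, true)
        ops = operating_points(sweep)
        rows = sweep.to_dict("records")
        best = max(rows, key=lambda r: (r["accuracy"], r["sensitivity"],
                                        -r["threshold"]))
        assert ops["max_accuracy"]["accuracy"] == best["accuracy"]
        assert ops["max_accuracy"]["threshold"] == best["threshold"]
        feas = [r for r in rows if r["sensitivity"] >= 0.90]
        best90 = max(feas, key=lambda r: (r["specificity"], r["accuracy"],
                                          -r["threshold"]))
        assert ops["sensitivity_90"]["specificity"] == best90["specificity"]

    def test_single_class_truth_flagged(self):
        sweep = classify_by_threshold([1.0, 2.0], [20.0, 30.0])
        ops = operating_points(sweep)
        assert "flag" in ops["max_accuracy"]


class TestErrorDifferenceHistogram:
    def test_identical_scores_all_near_zero(self):
        h = error_difference_histogram([1.0, 5.0], [3.0, 3.0], [3.0, 3.0])
        assert h["near_zero"] == 1.0

    def test_prediction_at_h2b_mass_positive(self):
        # pred == h2b, bdi far away: |pred-bdi| - |pred-h2b| strongly > 0
        h = error_difference_histogram([20.0] * 4, [40.0] * 4, [20.0] * 4)
        positive = h["h2b_2_6"] + h["h2b_6_13"] + h["h2b_ge13"]
        assert positive == 1.0 and h["h2b_ge13"] == 1.0

    def test_fractions_sum_to_one_and_match_counting(self):
        rng = np.random.default_rng(13)
        pred = rng.uniform(0, 60, 200)
        bdi = rng.uniform(0, 60, 200)
        h2b = rng.uniform(0, 60, 200)
        h = error_difference_histogram(pred, bdi, h2b)
        assert sum(h.values()) == pytest.approx(1.0, abs=1e-12)
        d = np.abs(pred - bdi) - np.abs(pred - h2b)
        assert h["near_zero"] == pytest.approx(np.mean(np.abs(d) < 2))
        assert h["h2b_6_13"] == pytest.approx(np.mean((d >= 6) & (d < 13)))
        assert h["bdi_2_6"] == pytest.approx(np.mean((d > -6) & (d <= -2)))


class TestComparisonTests:
    def test_identical_pairs_p_one(self):
        assert comparison_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                "paired_t") == 1.0
        assert comparison_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                "wilcoxon_signed_ranks") == 1.0

    def test_equal_correlations_fisher_p_one(self):
        p = comparison_tests(0.5, 0.5, "fisher_r_to_z", n_a=50, n_b=50)
        assert p == pytest.approx(1.0)

    def test_fisher_detects_large_difference(self):
        p = comparison_tests(0.9, 0.1, "fisher_r_to_z", n_a=100, n_b=100)
        assert p < 1e-6

    def test_wilcoxon_small_n_matches_exact_enumeration(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=6)
        y = x + rng.normal(size=6) * 0.5 + 0.3
        p_pkg = comparison_tests(x, y, "wilcoxon_signed_ranks")
        # brute-force null: all 2^6 sign assignments of |d| ranks
        di = x - y
        ranks = stats.rankdata(np.abs(di))
        w_obs = ranks[di > 0].sum()
        n = len(di)
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=n)]
        mean_w = np.mean(stats_all)
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12
                           for w in stats_all])
        assert p_pkg == pytest.approx(p_exact, abs=1e-10)

    def test_paired_t_agrees_with_scipy(self):
        rng = np.random.default_rng(19)
        a = rng.normal(size=20)
        b = a + 0.5 + rng.normal(size=20)
        assert comparison_tests(a, b, "paired_t") == pytest.approx(
            stats.ttest_rel(a, b).pvalue)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            comparison_tests([1.0, 2.0], [1.0, 2.0], "anova")


class TestBuildReport:
    def make_inputs(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        sev = rng.uniform(0, 1, n)
        subjects = pd.DataFrame({
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "gender": rng.choice(["male", "female"], n),
            "bdi": np.clip(np.round(63 * sev + rng.normal(0, 6, n)), 0, 63),
        })
        hamd_idx = rng.choice(n, size=n // 5, replace=False)
        subjects["hamd"] = np.nan
        subjects.loc[hamd_idx, "hamd"] = np.clip(
            np.round(48 * sev[hamd_idx] + rng.normal(0, 3, len(hamd_idx))),
            0, 48)
        from depspeech.scales import assign_h2b
        subjects = assign_h2b(subjects)
        preds = pd.DataFrame({
            "subject_id": subjects["subject_id"],
            "gender": subjects["gender"],
            "y_pred": 63 * sev + rng.normal(0, 5, n),
        })
        return preds, subjects

    def test_report_contains_all_table_shapes(self):
        preds, subjects = self.make_inputs()
        rep = build_report(preds, preds, subjects)
        for trained in ("bdi_trained", "h2b_trained"):
            for set_name in ("I", "II", "All"):
                block = rep["regression"][trained][set_name]
                assert "target_bdi" in block and "target_h2b" in block
                m = block["target_h2b"]["both"]
                assert np.isfinite(m["rmse"]) and m["rmse"] >= m["mae"]
        assert "set_II" in rep["comparison"]
        assert "error_difference_histogram" in rep["comparison"]
        assert np.isfinite(rep["classification"]["h2b_trained"]["auc"])

    def test_questionnaire_comparison_on_set_ii_only(self):
        preds, subjects = self.make_inputs(seed=1)
        rep = build_report(preds, preds, subjects)
        set2 = subjects[subjects["set"] == "II"]
        expected = regression_metrics(set2["bdi"], set2["h2b"])
        got = rep["comparison"]["set_II"]["bdi_questionnaire"]
        assert got["rmse"] == pytest.approx(expected["rmse"])

    def test_near_perfect_predictions_near_zero_rmse(self):
        preds, subjects = self.make_inputs(seed=2)
        perfect = preds.assign(y_pred=subjects["h2b"].astype(float))
        rep = build_report(perfect, perfect, subjects)
        m = rep["regression"]["h2b_trained"]["All"]["target_h2b"]["both"]
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)


class TestPlots:
    def test_plot_helpers_write_files(self, tmp_path):
        from depspeech.evaluation import plot_predictions, plot_roc
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 60, 30)
        p = t + rng.normal(0, 5, 30)
        plot_predictions(p, t, tmp_path / "scatter.png")
        pts, auc = roc_auc(classify_by_threshold(p, t))
        plot_roc(pts, auc, tmp_path / "roc.png")
        assert (tmp_path / "scatter.png").stat().st_size > 0
        assert (tmp_path / "roc.png").stat().st_size > 0
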