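"""Stratified folds, operating-point metrics, discrimination and
calibration, bootstrap intervals, subgroup robustness."""

import numpy as np
import pytest

from agfn.evaluate import (ConfusionCounts, bootstrap_ci, calibration,
                           confusion_metrics, discrimination, make_folds,
                           mean_auc, select_threshold, subgroup_metrics)


def auc_rank_oracle(y, s):
    """All-pairs comparison with half credit for ties (independent oracle)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFolds:
    def test_fold_sizes_balanced(self, rng):
        y = (rng.random((1000, 6)) < 0.15).astype(int)
        plan = make_folds(y, K=5, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_prevalence_preserved_per_fold(self, rng):
        y = (rng.random((1000, 1)) < 0.10).astype(int)
        plan = make_folds(y, K=5, seed=1)
        for f in plan.folds:
            prev = y[f, 0].mean()
            assert 0.08 <= prev <= 0.12

    def test_same_seed_reproduces_folds(self, rng):
        y = (rng.random((200, 6)) < 0.2).astype(int)
        a = make_folds(y, K=5, seed=4)
        b = make_folds(y, K=5, seed=4)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_partitions_disjoint_and_exhaustive(self, rng):
        y = (rng.random((173, 6)) < 0.2).astype(int)
        plan = make_folds(y, K=5, seed=2)
        plan.audit()

    def test_rare_outcome_warns(self, rng):
        y = np.zeros((50, 2), int)
        y[:2, 0] = 1
        y[::3, 1] = 1
        with pytest.warns(UserWarning, match="fewer than"):
            make_folds(y, K=5, seed=0)


class TestConfusion:
    def test_reported_operating_point_counts(self):
        # screening operating point: 249/271 cases found, 1272/1429 correct
        # negatives, 249 of 406 flags true
        c = ConfusionCounts(tp=249, fp=157, tn=1272, fn=22)
        m = confusion_metrics(c)
        assert round(m["sensitivity"], 2) == 0.92
        assert round(m["specificity"], 2) == 0.89
        assert round(m["ppv"], 2) == 0.61
        assert round(m["npv"], 2) == 0.98
        assert round(m["nns"], 1) == 1.6

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity",
                                         "ppv", "npv", "nns"))

    def test_balanced_quarters(self):
        m = confusion_metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert all(m[k] == 0.5 for k in ("sensitivity", "specificity",
                                         "ppv", "npv"))
        assert m["nns"] == 2.0

    def test_zero_denominator_yields_sentinel(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m["ppv"]) and np.isnan(m["nns"])
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestDiscrimination:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        d = discrimination(y, s)
        assert d["auc"] == 1.0 and d["auprc"] == 1.0

    def test_random_scores_near_half(self, rng):
        n = 4000
        y = (rng.random(n) < 0.5).astype(int)
        s = rng.random(n)
        se = np.sqrt(0.25 / min((y == 1).sum(), (y == 0).sum()))
        assert abs(discrimination(y, s)["auc"] - 0.5) < 3 * se

    def test_all_tied_scores_give_exactly_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert discrimination(y, np.full(5, 0.7))["auc"] == 0.5

    def test_single_class_yields_sentinel(self):
        assert np.isnan(discrimination(np.ones(5), np.random.rand(5))["auc"])

    def test_matches_rank_oracle(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        s = np.round(rng.random(200), 2)  # coarse grid forces ties
        assert discrimination(y, s)["auc"] == pytest.approx(
            auc_rank_oracle(y, s), abs=1e-12)

    def test_mean_auc_is_arithmetic_mean(self, rng):
        y = (rng.random((300, 3)) < 0.4).astype(int)
        p = rng.random((300, 3))
        per = [discrimination(y[:, k], p[:, k])["auc"] for k in range(3)]
        assert mean_auc(y, p) == pytest.approx(np.mean(per))


class TestThreshold:
    def test_raising_threshold_never_increases_sensitivity(self, rng):
        y = (rng.random(300) < 0.3).astype(int)
        p = rng.random(300)
        sens = []
        for t in np.linspace(0, 1, 21):
            pred = p >= t
            sens.append((pred & (y == 1)).sum() / (y == 1).sum())
        assert (np.diff(sens) <= 1e-12).all()

    def test_sens92_mode_meets_floor_on_validation(self, rng):
        y = (rng.random(500) < 0.3).astype(int)
        p = np.clip(0.5 * y + rng.random(500) * 0.6, 0, 1)
        t = select_threshold(y, p, mode="sens92")
        pred = p >= t
        assert (pred & (y == 1)).sum() / (y == 1).sum() >= 0.92

    def test_f1_mode_maximizes_f1(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        p = np.clip(0.6 * y + rng.random(200) * 0.5, 0, 1)
        t = select_threshold(y, p, mode="f1")
        best = discrimination(y, p, threshold=t)["f1"]
        for other in np.linspace(0.05, 0.95, 19):
            assert best >= discrimination(y, p, threshold=other)["f1"] - 1e-12


class TestCalibration:
    def test_perfect_binary_predictions_give_zero_brier(self):
        y = np.array([0, 1] * 10)
        cal = calibration(y, y.astype(float))
        assert cal["brier"] == 0.0

    def test_constant_half_gives_quarter_brier(self, rng):
        y = (rng.random(50) < 0.3).astype(int)
        assert calibration(y, np.full(50, 0.5))["brier"] == 0.25

    def test_well_calibrated_scores_recover_unit_slope(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(0.02, 0.98, 10_000)
        y = (rng.random(10_000) < p).astype(int)
        cal = calibration(y, p)
        assert 0.9 <= cal["slope"] <= 1.1
        assert abs(cal["in_the_large"]) < 0.1

    def test_reliability_table_counts_sum(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        p = rng.random(200)
        cal = calibration(y, p)
        assert cal["reliability"]["count"].sum() == 200

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibration(np.array([0, 1] * 10), np.full(20, 1.2))


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        y, p = rng.random(50), rng.random(50)
        lo, hi = bootstrap_ci(lambda a, b: 3.14, y, p, B=100, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_reproduces_interval(self, rng):
        y = (rng.random(100) < 0.4).astype(int)
        p = rng.random(100)
        f = lambda a, b: float(np.mean(b[a == 1]))
        assert bootstrap_ci(f, y, p, B=200, seed=5) == \
            bootstrap_ci(f, y, p, B=200, seed=5)

    def test_coverage_close_to_nominal(self):
        rng = np.random.default_rng(7)
        covered = 0
        outer = 150
        for _ in range(outer):
            x = rng.normal(size=100)
            lo, hi = bootstrap_ci(lambda a, b: float(a.mean()), x, x,
                                  B=200, seed=int(rng.integers(2**31)))
            covered += lo <= 0 <= hi
        assert abs(covered / outer - 0.95) <= 0.05

    def test_mostly_undefined_metric_warns_na(self, rng):
        y = np.zeros(20)
        p = rng.random(20)

        def frail(a, b):
            raise ValueError("undefined")

        with pytest.warns(UserWarning, match="undefined"):
            lo, hi = bootstrap_ci(frail, y, p, B=100, seed=0)
        assert np.isnan(lo) and np.isnan(hi)


class TestSubgroups:
    def test_identical_distributions_have_tiny_deviation(self, rng):
        n = 4000
        p = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < p).astype(int)
        groups = rng.integers(0, 2, n)
        rep = subgroup_metrics(y, p, groups)
        assert rep["max_auc_deviation"] < 0.05
        assert rep["max_brier_deviation"] < 0.02

    def test_miscalibrated_site_has_larger_brier(self, rng):
        n = 2000
        p = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < p).astype(int)
        groups = np.where(np.arange(n) < 300, "siteA", "siteB")
        p_bad = p.copy()
        p_bad[:300] = np.clip(p_bad[:300] + 0.4, 0.01, 0.99)  # inject shift
        rep = subgroup_metrics(y, p_bad, groups)
        assert rep["groups"]["siteA"]["brier"] > rep["pooled"]["brier"]

    def test_degenerate_group_skipped_with_warning(self, rng):
        y = np.array([0, 1, 0, 1, 1])
        p = rng.random(5)
        groups = np.array(["a", "a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="degenerate"):
            rep = subgroup_metrics(y, p, groups)
        assert "b" not in rep["groups"]
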