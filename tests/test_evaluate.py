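"""Cross-validation plans, ROC/AUC, confidence intervals and bookkeeping."""

import numpy as np
import pytest

from mammica.evaluate import (
    imbalance_percent,
    make_cv_plan,
    mean_auc_ci,
    percent_change,
    prototype_table,
    roc_curve,
    run_experiment,
)
from mammica.roi import ROIPatch


def mann_whitney_auc(scores, labels):
    """Brute-force tie-aware pairwise AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


class TestCvPlan:
    def test_thirty_ids_one_per_test_fold(self):
        plan = make_cv_plan(np.arange(30), seed=0)
        assert all(len(f["test"]) == 1 for f in plan.folds)

    @pytest.mark.parametrize("n", [30, 97, 533, 5052])
    def test_partition_and_split_accounting(self, n):
        ids = np.arange(n)
        plan = make_cv_plan(ids, n_folds=30, val_frac=0.2, seed=3)
        seen = np.concatenate([f["test"] for f in plan.folds])
        assert sorted(seen) == list(ids)  # each id tested exactly once
        for f in plan.folds:
            tr, va, te = f["train"], f["val"], f["test"]
            assert len(tr) + len(va) + len(te) == n
            assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
            rest = len(tr) + len(va)
            assert abs(len(tr) - 0.8 * rest) <= 0.5  # 80:20 within one prototype

    def test_expected_fold_sizes_at_study_scale(self):
        plan = make_cv_plan(np.arange(5052), n_folds=30, seed=1)
        assert np.mean([len(f["test"]) for f in plan.folds]) == pytest.approx(168.4)
        fracs = [
            len(f["train"]) / (len(f["train"]) + len(f["val"])) for f in plan.folds
        ]
        assert abs(np.mean(fracs) - 0.8) < 0.01

    def test_too_few_prototypes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_cv_plan(np.arange(10), n_folds=30)

    def test_deterministic_under_seed(self):
        a = make_cv_plan(np.arange(100), seed=5)
        b = make_cv_plan(np.arange(100), seed=5)
        for fa, fb in zip(a.folds, b.folds):
            for key in ("train", "val", "test"):
                np.testing.assert_array_equal(fa[key], fb[key])


class TestRocCurve:
    def test_perfect_scores_auc_one(self):
        labels = np.array([0, 1, 0, 1, 1])
        assert roc_curve(labels.astype(float), labels).auc == 1.0

    def test_all_tied_scores_chance_diagonal(self):
        roc = roc_curve(np.full(10, 0.5), np.array([0, 1] * 5))
        assert roc.auc == pytest.approx(0.5)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.arange(4.0), np.ones(4))

    def test_curve_monotone_and_auc_trapezoidal(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)

    def test_auc_equals_mann_whitney_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            assert roc_curve(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_reversed_scores_mirror_auc(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        base = roc_curve(scores, labels).auc
        assert roc_curve(3.0 * scores + 7.0, labels).auc == pytest.approx(base)
        assert roc_curve(np.exp(scores), labels).auc == pytest.approx(base)


class TestSummaryStatistics:
    def test_constant_aucs_degenerate_interval(self):
        mean, lo, hi = mean_auc_ci([0.9] * 30)
        assert (mean, lo, hi) == pytest.approx((0.9, 0.9, 0.9))

    def test_interval_symmetric_about_mean(self, rng):
        vals = rng.uniform(0.7, 1.0, size=30)
        mean, lo, hi = mean_auc_ci(vals)
        assert mean - lo == pytest.approx(hi - mean, abs=1e-12)

    def test_hand_computed_t_interval(self):
        # for [0.90, 0.92, 0.95, 0.89, 0.94]: mean .92, s = 0.0254951,
        # t_{.975,4} = 2.7764451 -> half-width 0.0316563
        mean, lo, hi = mean_auc_ci([0.90, 0.92, 0.95, 0.89, 0.94])
        assert mean == pytest.approx(0.92)
        assert lo == pytest.approx(0.8883437, abs=1e-6)
        assert hi == pytest.approx(0.9516563, abs=1e-6)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_auc_ci([0.9])

    def test_percent_change_two_decimals(self):
        assert percent_change(0.965, 0.892) == -7.56
        assert percent_change(0.964, 0.897) == -6.95
        assert percent_change(0.5, 0.5) == 0.00
        with pytest.raises(ValueError):
            percent_change(0.0, 0.5)

    def test_imbalance_percent_rounding(self):
        assert imbalance_percent(236.3, 238.9, 559.6) == 15
        assert imbalance_percent(78.9, 108.3, 432.9) == 57
        assert imbalance_percent(10.0, 20.0, 30.0) == 0
        with pytest.raises(ValueError):
            imbalance_percent(1, 1, 0)


def toy_patches(n_mass, n_normal, seed=0, side=8, density=2):
    """Trivially separable patches: bright blobs vs dim noise."""
    rng = np.random.default_rng(seed)
    patches = []
    for i in range(n_mass):
        pix = np.clip(0.3 + 0.5 * np.exp(
            -((np.arange(side) - side / 2) ** 2 / 8)[:, None]
            - ((np.arange(side) - side / 2) ** 2 / 8)[None, :]
        ) + rng.normal(0, 0.05, (side, side)), 0, 1)
        patches.append(ROIPatch(pix, "malignant" if i % 2 else "benign", density, f"m{i}"))
    for i in range(n_normal):
        pix = np.clip(0.3 + rng.normal(0, 0.05, (side, side)), 0, 1)
        patches.append(ROIPatch(pix, "normal", density, f"n{i}"))
    return patches


class TestPrototypeTable:
    def test_totals_and_conservation(self):
        patches = toy_patches(20, 25, density=2)
        plan = make_cv_plan(np.arange(len(patches)), n_folds=9, seed=0)
        table = prototype_table(plan, patches)
        # totals column equals sum of cells per row
        np.testing.assert_allclose(
            table["total"], table.drop(columns="total").sum(axis=1)
        )
        # each fold partitions the whole set, so per-row mean counts sum to N
        assert table.loc[2, "total"] == pytest.approx(45)
        assert table.loc["overall", "total"] == pytest.approx(45)

    def test_single_density_overall_row_equals_density_row(self):
        patches = toy_patches(12, 18, density=3)
        plan = make_cv_plan(np.arange(len(patches)), n_folds=6, seed=1)
        table = prototype_table(plan, patches)
        np.testing.assert_allclose(table.loc[3], table.loc["overall"])


FAST = dict(
    n_components=3, n_folds=5,
    hidden_grid=(20,), mlp_restarts=1, mlp_max_epochs=60, mlp_patience=10,
    gamma_grid=(0.1, 1.0), C_grid=(1.0, 10.0),
)


class TestRunExperiment:
    def test_separable_classes_high_auc_both_kinds(self):
        patches = toy_patches(40, 40, seed=1)
        res = run_experiment(patches, classifier="both", seed=0, **FAST)
        assert res["mlp"].mean_auc > 0.95
        assert res["svm"].mean_auc > 0.95

    def test_permuted_labels_ci_contains_half(self):
        patches = toy_patches(40, 40, seed=2)
        res = run_experiment(patches, classifier="svm", seed=0,
                             permute_labels=True, **FAST)
        lo, hi = res["svm"].ci95
        assert lo <= 0.5 <= hi

    def test_deterministic_result_bytes(self):
        patches = toy_patches(30, 30, seed=3)
        a = run_experiment(patches, classifier="svm", seed=4, **FAST)
        b = run_experiment(patches, classifier="svm", seed=4, **FAST)
        assert a["svm"].to_json() == b["svm"].to_json()

    def test_single_class_test_folds_skipped_with_warning(self):
        patches = toy_patches(56, 4, seed=5)
        with pytest.warns(UserWarning, match="single-class"):
            res = run_experiment(patches, classifier="svm", seed=0, **FAST)
        assert res["svm"].n_folds_skipped >= 1
        assert len(res["svm"].fold_aucs) + res["svm"].n_folds_skipped == 5

    def test_empty_stratum_rejected(self):
        patches = toy_patches(10, 10, density=2)
        with pytest.raises(ValueError, match="stratum"):
            run_experiment(patches, stratum="4", **FAST)
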