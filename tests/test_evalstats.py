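"""Metrics, ROC/AUC against brute-force oracles, bootstrap, Dice, LOPO."""

import itertools

import numpy as np
import pytest

from hsibrain.evalstats import (
    ConfusionCounts,
    bootstrap_metrics,
    dice,
    lopo_cv,
    metrics,
    roc_auc,
)


class TestMetrics:
    def test_perfect_counts(self):
        assert metrics(ConfusionCounts(10, 10, 0, 0)) == (1.0, 1.0, 1.0)

    def test_sensitivity_and_specificity_closed_form(self):
        acc, sens, spec = metrics(ConfusionCounts(TP=8, TN=9, FP=1, FN=2))
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)
        assert acc == pytest.approx(17 / 20)

    def test_zero_denominator_gives_nan_not_exception(self):
        _, sens, _ = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert np.isnan(sens)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


def brute_force_auc(scores, labels):
    """Mann-Whitney definition: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_best_youden(scores, labels):
    best = -np.inf
    for t in np.r_[np.unique(scores), scores.max() + 1]:
        pred = scores >= t
        tp = ((pred == 1) & (labels == 1)).sum()
        fn = ((pred == 0) & (labels == 1)).sum()
        tn = ((pred == 0) & (labels == 0)).sum()
        fp = ((pred == 1) & (labels == 0)).sum()
        best = max(best, tp / (tp + fn) + tn / (tn + fp) - 1)
    return best


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        _, auc, opt = roc_auc(scores, labels)
        assert auc == 1.0
        assert opt["sensitivity"] == 1.0 and opt["specificity"] == 1.0

    def test_inverted_labels_auc_zero(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        _, auc, _ = roc_auc(scores, labels)
        assert auc == 0.0

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, int))

    def test_agrees_with_brute_force_on_exhaustive_small_instances(self):
        """All label patterns at n=8 with tied and untied scores."""
        rng = np.random.default_rng(0)
        scores_sets = [np.arange(8.0), np.array([0, 1, 1, 2, 2, 2, 3, 3.0])]
        for scores in scores_sets:
            for pattern in itertools.product([0, 1], repeat=8):
                labels = np.array(pattern)
                if labels.min() == labels.max():
                    continue
                _, auc, opt = roc_auc(scores, labels)
                assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
                assert opt["youden_j"] == pytest.approx(
                    brute_force_best_youden(scores, labels), abs=1e-12
                )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = (0, 1)
        _, auc1, _ = roc_auc(scores, labels)
        _, auc2, _ = roc_auc(np.exp(3 * scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(2)
        n = 100_000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        _, auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.01)


class TestBootstrap:
    def test_all_correct_gives_degenerate_interval(self):
        gold = np.repeat([1, 2, 3], 20)
        report = bootstrap_metrics(gold, preds=gold.copy(), reps=200, rng=0)
        assert report.accuracy.mean == 1.0
        assert (report.accuracy.ci_low, report.accuracy.ci_high) == (1.0, 1.0)

    def test_balanced_resampling_draws_min_class_count(self):
        """Accuracy of a classifier that is perfect on the majority class but
        wrong on the minority converges to 0.5 under class balancing."""
        gold = np.r_[np.ones(500, int), 2 * np.ones(20, int)]
        preds = np.ones(520, int)  # always predicts class 1
        report = bootstrap_metrics(gold, preds=preds, reps=500, rng=1)
        assert report.accuracy.mean == pytest.approx(0.5, abs=1e-9)
        assert report.per_class[1]["sensitivity"].mean == 1.0
        assert report.per_class[2]["sensitivity"].mean == 0.0

    def test_auc_matches_roc_auc_on_full_sample_when_classes_balanced(self):
        rng = np.random.default_rng(3)
        n = 400
        gold = np.r_[np.zeros(n, int), np.ones(n, int)]
        scores1 = np.r_[rng.normal(0, 1, n), rng.normal(1.5, 1, n)]
        scores = np.column_stack([-scores1, scores1])
        _, auc_full, _ = roc_auc(scores1, gold)
        report = bootstrap_metrics(gold, preds=(scores1 > 0.75).astype(int),
                                   scores=scores, reps=300, rng=2)
        assert report.auc.mean == pytest.approx(auc_full, abs=0.02)
        assert report.auc.ci_low <= auc_full <= report.auc.ci_high

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_metrics(np.array([]), preds=np.array([]))

    def test_report_interval_brackets_mean(self):
        rng = np.random.default_rng(4)
        gold = rng.integers(1, 4, size=300)
        preds = np.where(rng.random(300) < 0.8, gold, rng.integers(1, 4, size=300))
        r = bootstrap_metrics(gold, preds=preds, reps=400, rng=5)
        for m in (r.accuracy, r.sensitivity, r.specificity):
            assert m.ci_low <= m.mean <= m.ci_high


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((6, 6)) < 0.4
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[2] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap_closed_form(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4], b[2:6] = True, True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class _Scene:
    def __init__(self, pid, tag):
        self.patient_id = pid
        self.tag = tag


class TestLopoCv:
    def make_cohort(self):
        return [_Scene(f"P{i}", j) for i in range(6) for j in range(2)]

    def test_one_fold_per_patient(self):
        cohort = self.make_cohort()
        results = lopo_cv(cohort, lambda tr: None, lambda m, te: len(te))
        assert len(results) == 6
        assert all(n == 2 for _, n in results)

    def test_test_patient_never_in_training(self):
        cohort = self.make_cohort()
        seen = {}

        def train_fn(train_scenes):
            return {s.patient_id for s in train_scenes}

        def eval_fn(train_pids, test_scenes):
            seen[test_scenes[0].patient_id] = train_pids
            return None

        lopo_cv(cohort, train_fn, eval_fn)
        for pid, train_pids in seen.items():
            assert pid not in train_pids

    def test_single_patient_is_error(self):
        with pytest.raises(ValueError):
            lopo_cv([_Scene("P0", 0)], lambda t: None, lambda m, t: None)
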