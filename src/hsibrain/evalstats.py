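"""Validation statistics: confusion metrics, ROC/AUC, class-balanced
bootstrap, Dice, and the leave-one-patient-out harness.

The bootstrap follows the class-balancing protocol of the intraoperative
study: the smallest class in the test image sets the resample size m; each
replicate draws m samples with replacement from every class, computes the
metrics on the balanced resample, and 1000 replicates yield the mean and
the 2.5/97.5-percentile 95% confidence interval.  Multiclass sensitivity,
specificity and AUC are one-vs-rest per class and then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSummary",
    "MetricReport",
    "metrics",
    "roc_auc",
    "bootstrap_metrics",
    "dice",
    "lopo_cv",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; P = TP+FN positives, N = TN+FP negatives."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclass
class MetricSummary:
    """Point value with a bootstrap percentile confidence interval."""

    mean: float
    ci_low: float
    ci_high: float


@dataclass
class MetricReport:
    accuracy: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    auc: MetricSummary | None = None
    per_class: dict[int, dict[str, MetricSummary]] = field(default_factory=dict)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from binary confusion counts.

    accuracy = (TP+TN)/(P+N); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  A zero denominator yields ``nan`` for that
    metric (undefined, not an exception).
    """
    total = counts.P + counts.N
    if total == 0:
        raise ValueError("no evaluated samples")
    acc = (counts.TP + counts.TN) / total
    sens = counts.TP / counts.P if counts.P > 0 else float("nan")
    spec = counts.TN / counts.N if counts.N > 0 else float("nan")
    return acc, sens, spec


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC curve, trapezoid AUC, and the Youden-optimal operating point.

    ``labels`` are binary (1 = positive).  Equal scores are grouped into a
    single threshold step.  The optimal operating point maximizes Youden's
    J = sensitivity + specificity - 1.

    Returns ``(points, auc, optimal)`` where ``points`` is an array of
    (fpr, tpr, threshold) rows and ``optimal`` a dict with the chosen
    threshold, sensitivity and specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    k = int(np.argmax(j))
    optimal = {
        "threshold": float(thr[k]),
        "sensitivity": float(tpr[k]),
        "specificity": float(1.0 - fpr[k]),
        "youden_j": float(j[k]),
    }
    points = np.column_stack([fpr, tpr, thr])
    return points, auc, optimal


def _auc_from_ranks(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Rank-statistic (Mann-Whitney) AUC along axis 1, tie-aware."""
    ranks = rankdata(scores, axis=1)
    n_pos = positive.sum(axis=1)
    n_neg = positive.shape[1] - n_pos
    r_pos = np.where(positive, ranks, 0.0).sum(axis=1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _summary(values: np.ndarray) -> MetricSummary:
    return MetricSummary(
        float(np.nanmean(values)),
        float(np.nanpercentile(values, 2.5)),
        float(np.nanpercentile(values, 97.5)),
    )


def bootstrap_metrics(
    gold: np.ndarray,
    preds: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> MetricReport:
    """Class-balanced bootstrap of accuracy/sensitivity/specificity (and
    AUC when per-class ``scores`` are given).

    ``gold`` holds integer class labels; ``preds`` discrete predictions of
    the same shape; ``scores`` an optional ``(n, K)`` array of per-class
    scores aligned with ``sorted(unique(gold))``.  Every replicate draws
    ``m = min class count`` samples with replacement from each class so
    all classes contribute equally.
    """
    if preds is None and scores is None:
        raise ValueError("need preds and/or scores")
    gold = np.asarray(gold).ravel()
    if preds is not None:
        preds = np.asarray(preds).ravel()
        if preds.shape != gold.shape:
            raise ValueError("preds shape does not match gold")
    rng = np.random.default_rng(rng)
    classes = np.unique(gold)
    idx_by_class = [np.flatnonzero(gold == c) for c in classes]
    counts = [len(ix) for ix in idx_by_class]
    if min(counts) == 0:
        raise ValueError("every evaluated class needs at least one sample")
    m = min(counts)

    # (reps, K, m) resampled flat indices, one block of m draws per class
    draws = np.stack(
        [ix[rng.integers(0, len(ix), size=(reps, m))] for ix in idx_by_class], axis=1
    )

    per_class: dict[int, dict[str, np.ndarray]] = {int(c): {} for c in classes}
    if preds is not None:
        pred_draw = preds[draws]  # (reps, K, m)
        acc = np.mean(pred_draw == classes[None, :, None], axis=(1, 2))
        for k, c in enumerate(classes):
            sens_c = np.mean(pred_draw[:, k, :] == c, axis=1)
            others = np.delete(pred_draw, k, axis=1).reshape(reps, -1)
            spec_c = np.mean(others != c, axis=1)
            per_class[int(c)]["sensitivity"] = sens_c
            per_class[int(c)]["specificity"] = spec_c
        sens = np.mean([per_class[int(c)]["sensitivity"] for c in classes], axis=0)
        spec = np.mean([per_class[int(c)]["specificity"] for c in classes], axis=0)
    else:
        acc = sens = spec = np.full(reps, np.nan)

    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores]) if classes.size == 2 else None
        if scores is None or scores.shape != (gold.size, classes.size):
            raise ValueError("scores must be (n_samples, n_classes)")
        flat_draws = draws.reshape(reps, -1)  # (reps, K*m)
        aucs = []
        for k, c in enumerate(classes):
            s = scores[flat_draws, k]
            pos = gold[flat_draws] == c
            auc_c = _auc_from_ranks(s, pos)
            per_class[int(c)]["auc"] = auc_c
            aucs.append(auc_c)
        auc = np.mean(aucs, axis=0)

    report = MetricReport(
        accuracy=_summary(acc),
        sensitivity=_summary(sens),
        specificity=_summary(spec),
        auc=_summary(auc) if auc is not None else None,
        per_class={
            c: {name: _summary(vals) for name, vals in d.items()}
            for c, d in per_class.items()
        },
    )
    return report


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def lopo_cv(cohort, train_fn, eval_fn) -> list[tuple[str, object]]:
    """Leave-one-patient-out cross-validation.

    ``cohort`` is a sequence of objects with a ``patient_id`` attribute.
    For each patient, ``train_fn(train_scenes)`` fits models on every
    other patient's scenes and ``eval_fn(models, test_scenes)`` evaluates
    on the held-out patient's scenes.  Returns ``(patient_id, result)``
    pairs in patient order.
    """
    patient_ids = []
    for scene in cohort:
        if scene.patient_id not in patient_ids:
            patient_ids.append(scene.patient_id)
    if len(patient_ids) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    results = []
    for pid in patient_ids:
        train_scenes = [s for s in cohort if s.patient_id != pid]
        test_scenes = [s for s in cohort if s.patient_id == pid]
        models = train_fn(train_scenes)
        results.append((pid, eval_fn(models, test_scenes)))
    return results
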