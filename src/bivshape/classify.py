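"""Leave-one-out kNN classification of subjects from a scalar shape feature.

The classifier mirrors a clinical screening question: given one number
per subject (a currents distance to the control mean, or a summed
loading score), how well does it separate patients from controls?  Each
subject is classified by the majority label of its k nearest neighbours
(k = 3 by default) among the other n - 1 subjects, and the fraction of
patient neighbours is reported as a class probability.  Confusion
metrics follow the per-group convention: sensitivity is the accuracy on
patients, specificity the accuracy on controls.  ROC analysis sweeps
all thresholds of the score; the operating cut-off maximises accuracy
with sensitivity as tie-breaker — for a potentially lethal disease a
missed patient costs more than a false alarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedMetricError

POSITIVE_LABEL = "ARVC"
NEGATIVE_LABEL = "control"


@dataclass(frozen=True)
class LooPrediction:
    """One subject's leave-one-out prediction."""

    subject_id: object
    true_label: str
    predicted_label: str
    probability_arvc: float  # fraction of the k neighbours labelled ARVC


@dataclass(frozen=True)
class ClassifierReport:
    """Confusion metrics plus ROC summary for one scalar feature."""

    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (T, 2) of (FPR, TPR), threshold-descending
    auc: float
    optimal_cutoff: float


def knn_loo(
    features,
    labels,
    k: int = 3,
    subject_ids=None,
) -> list[LooPrediction]:
    """Leave-one-out k-nearest-neighbour predictions on a scalar feature.

    For each subject the k smallest |feature_i - feature_j| over the
    other n - 1 subjects define the neighbourhood; distance ties are
    broken toward the lower subject index (deterministic and recorded).
    Predicted label is the neighbourhood majority; the reported
    probability is the ARVC fraction among the neighbours.
    """
    f = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    n = f.size
    if labels.size != n:
        raise InvalidArgumentError("features and labels must have equal length")
    if np.any(~np.isfinite(f)):
        raise InvalidArgumentError("features must be finite (no missing values)")
    if n <= k:
        raise InsufficientDataError(f"need more than k={k} subjects, got {n}")
    ids = np.arange(n) if subject_ids is None else np.asarray(subject_ids, dtype=object)

    predictions = []
    for i in range(n):
        others = np.delete(np.arange(n), i)
        dist = np.abs(f[others] - f[i])
        order = np.lexsort((others, dist))  # distance, then lower index
        neigh = others[order[:k]]
        p_arvc = float(np.mean(labels[neigh] == POSITIVE_LABEL))
        pred = POSITIVE_LABEL if p_arvc > 0.5 else NEGATIVE_LABEL
        predictions.append(
            LooPrediction(ids[i], str(labels[i]), pred, p_arvc)
        )
    return predictions


def confusion_metrics(
    predictions: list[LooPrediction],
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from LOO predictions.

    Sensitivity is the fraction of ARVC subjects predicted ARVC;
    specificity the fraction of controls predicted control.
    """
    true = np.array([p.true_label for p in predictions])
    pred = np.array([p.predicted_label for p in predictions])
    n_pos = int(np.sum(true == POSITIVE_LABEL))
    n_neg = int(np.sum(true == NEGATIVE_LABEL))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present")
    correct = pred == true
    sensitivity = float(np.mean(correct[true == POSITIVE_LABEL]))
    specificity = float(np.mean(correct[true == NEGATIVE_LABEL]))
    accuracy = float(np.mean(correct))
    return accuracy, sensitivity, specificity


def roc_and_cutoff(score, labels, k: int | None = None) -> ClassifierReport:
    """ROC curve, AUC and accuracy-optimal threshold for a scalar score.

    Subjects with score strictly above a threshold are classed ARVC.
    All distinct scores (plus sentinels for the all-positive and
    all-negative rules) serve as candidate thresholds; AUC is the
    trapezoid-rule area.  The optimal cut-off maximises accuracy, ties
    broken toward higher sensitivity, then toward the lower threshold.
    A constant score degenerates to a single ROC point and AUC 0.5.
    """
    s = np.asarray(score, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    y = labels == POSITIVE_LABEL
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present")

    if np.ptp(s) == 0:
        import warnings

        warnings.warn("constant score: degenerate single-point ROC", stacklevel=2)
        fpr = np.array([[1.0, 1.0]])
        acc = max(n_pos, n_neg) / s.size
        return ClassifierReport(
            accuracy=acc,
            sensitivity=1.0 if n_pos >= n_neg else 0.0,
            specificity=0.0 if n_pos >= n_neg else 1.0,
            roc_points=fpr,
            auc=0.5,
            optimal_cutoff=float(s[0]),
        )

    distinct = np.unique(s)
    # thresholds: below min (everything positive) through each distinct score
    thresholds = np.concatenate([[distinct[0] - 1.0], distinct])
    points = []
    best = None  # (accuracy, sensitivity, -threshold)
    for t in thresholds:
        pred_pos = s > t
        tpr = float(np.sum(pred_pos & y) / n_pos)
        fpr = float(np.sum(pred_pos & ~y) / n_neg)
        acc = float((np.sum(pred_pos & y) + np.sum(~pred_pos & ~y)) / s.size)
        points.append((fpr, tpr))
        key = (acc, tpr, -t)
        if best is None or key > best[0]:
            best = (key, t)
    roc = np.array(points)
    roc_sorted = roc[::-1]  # thresholds ascend -> reverse for ascending FPR
    auc = float(np.trapezoid(roc_sorted[:, 1], roc_sorted[:, 0]))
    t_best = best[1]
    pred_pos = s > t_best
    sens = float(np.sum(pred_pos & y) / n_pos)
    spec = float(np.sum(~pred_pos & ~y) / n_neg)
    acc = float((np.sum(pred_pos & y) + np.sum(~pred_pos & ~y)) / s.size)
    return ClassifierReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        roc_points=roc_sorted,
        auc=auc,
        optimal_cutoff=float(t_best),
    )
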