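"""Diagnostic test statistics for patient-level PE classification.

All statistics derive from the 2x2 confusion matrix of per-examination
decisions: sensitivity, specificity, accuracy, balanced accuracy, the
Matthews correlation coefficient (MCC), Wilson score confidence
intervals for the proportions, and ROC/AUROC over case-level predicted
embolus volumes.

Conventions
-----------
* MCC is defined as 0 when any marginal of the confusion matrix is
  empty (the standard convention; avoids NaNs during grid search).
* Proportion CIs use the Wilson score interval (via statsmodels) with
  an exactly computed normal quantile.
* MCC CIs use a seeded stratified parametric bootstrap (cases resampled
  within their true class).
* ROC thresholds follow the classifier's decision boundary: a case is
  called positive when its volume score strictly exceeds the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "RocCurve",
    "confusion_matrix",
    "mcc",
    "wilson_interval",
    "metric_set",
    "roc_by_volume",
    "pooled_evaluation",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level TP/FP/TN/FN counts — the atom of every statistic."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """Point metrics with confidence intervals for one confusion matrix.

    Proportions are in [0, 1] (``None`` when the defining class is
    absent); ``ci`` maps metric name to (low, high) bounds.
    """

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    balanced_accuracy: float | None
    mcc: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    auroc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.cm.tp,
            "fp": self.cm.fp,
            "tn": self.cm.tn,
            "fn": self.cm.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        return d


@dataclass
class RocCurve:
    """ROC curve over the volume-threshold axis.

    ``fpr``/``tpr`` are ordered from (0, 0) to (1, 1); ``thresholds``
    holds the volume threshold (mm^3) producing each interior point.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_matrix(records: Iterable) -> ConfusionMatrix:
    """Tally patient-level decisions into a confusion matrix.

    ``records`` may be case records (with ``label``/``predicted``
    attributes) or ``(label, predicted)`` pairs.
    """
    tp = fp = tn = fn = 0
    for r in records:
        if hasattr(r, "label"):
            label, pred = r.label, r.predicted
        else:
            label, pred = r
        if label is None or pred is None:
            raise ValueError("record missing label or prediction")
        if label not in (0, 1) or pred not in (0, 1):
            raise ValueError(f"labels/predictions must be 0/1, got {(label, pred)}")
        if label == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 if a marginal is empty."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact integer
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def wilson_interval(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    The normal quantile is computed exactly from the confidence level
    rather than hard-coded; bounds are clipped into [0, 1].
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1.0 - confidence, method="wilson")
    # the Wilson bound is exactly 0 (resp. 1) at k = 0 (resp. k = n);
    # snap away float residue so boundary cases are exact
    low = 0.0 if k == 0 else float(np.clip(low, 0.0, 1.0))
    high = 1.0 if k == n else float(np.clip(high, 0.0, 1.0))
    return low, high


def _mcc_bootstrap_ci(
    cm: ConfusionMatrix,
    confidence: float,
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Stratified parametric bootstrap CI for the MCC.

    True positives / negatives are resampled as binomial draws within
    each true class (class sizes fixed), matching resampling cases with
    replacement inside their stratum.
    """
    rng = np.random.default_rng(seed)
    n_pos, n_neg = cm.n_positive, cm.n_negative
    p_sens = cm.tp / n_pos if n_pos else 0.0
    p_spec = cm.tn / n_neg if n_neg else 0.0
    tps = rng.binomial(n_pos, p_sens, size=n_boot) if n_pos else np.zeros(n_boot, int)
    tns = rng.binomial(n_neg, p_spec, size=n_boot) if n_neg else np.zeros(n_boot, int)
    fps = n_neg - tns
    fns = n_pos - tps
    num = tps * tns - fps * fns
    denom = np.sqrt(
        (tps + fps).astype(float)
        * (tps + fns)
        * (tns + fps)
        * (tns + fns)
    )
    vals = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(vals, [alpha / 2, 1.0 - alpha / 2])
    return float(lo), float(hi)


def metric_set(
    cm: ConfusionMatrix,
    confidence: float = 0.95,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> MetricSet:
    """All point metrics plus confidence intervals for one matrix.

    Wilson intervals for sensitivity, specificity, and accuracy; a
    seeded stratified bootstrap for the MCC. A metric whose defining
    class is absent (e.g. sensitivity with no positive cases) is
    reported as ``None`` rather than raising.
    """
    sens = cm.tp / cm.n_positive if cm.n_positive else None
    spec = cm.tn / cm.n_negative if cm.n_negative else None
    acc = (cm.tp + cm.tn) / cm.n
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    ci: dict[str, tuple[float, float]] = {}
    if sens is not None:
        ci["sensitivity"] = wilson_interval(cm.tp, cm.n_positive, confidence)
    if spec is not None:
        ci["specificity"] = wilson_interval(cm.tn, cm.n_negative, confidence)
    ci["accuracy"] = wilson_interval(cm.tp + cm.tn, cm.n, confidence)
    if bootstrap_reps > 0:
        ci["mcc"] = _mcc_bootstrap_ci(cm, confidence, bootstrap_reps, seed)
    return MetricSet(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bal,
        mcc=mcc(cm),
        ci=ci,
    )


def roc_by_volume(
    scores: Sequence[float] | Iterable,
    labels: Sequence[int] | None = None,
) -> RocCurve:
    """ROC curve and AUROC from case-level volume scores.

    Accepts either parallel ``scores``/``labels`` sequences or an
    iterable of case records carrying ``score`` and ``label``. A case is
    predicted positive when its score strictly exceeds the volume
    threshold; sweeping the threshold over all distinct scores traces
    the curve, with (0, 0) and (1, 1) appended. The trapezoidal AUC
    equals the Mann-Whitney probability of ranking a random positive
    above a random negative, ties counted half.
    """
    if labels is None:
        records = list(scores)
        score_arr = np.array([r.score for r in records], dtype=float)
        label_arr = np.array([r.label for r in records], dtype=int)
    else:
        score_arr = np.asarray(scores, dtype=float)
        label_arr = np.asarray(labels, dtype=int)
    n_pos = int((label_arr == 1).sum())
    n_neg = int((label_arr == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"ROC needs both classes; no {missing} cases")

    thresholds = np.unique(score_arr)[::-1]  # descending
    tpr = [( (score_arr[label_arr == 1] > t).sum() ) / n_pos for t in thresholds]
    fpr = [( (score_arr[label_arr == 0] > t).sum() ) / n_neg for t in thresholds]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    # strictly ordered sweep: drop duplicate consecutive points
    keep = np.ones(len(fpr), dtype=bool)
    keep[1:] = (np.diff(fpr) != 0) | (np.diff(tpr) != 0)
    fpr, tpr = fpr[keep], tpr[keep]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc
    )


def pooled_evaluation(
    matrices: Sequence[ConfusionMatrix], **kwargs
) -> MetricSet:
    """Element-wise pool of confusion matrices, then ``metric_set``."""
    if not matrices:
        raise ValueError("need at least one confusion matrix")
    total = matrices[0]
    for m in matrices[1:]:
        total = total + m
    return metric_set(total, **kwargs)
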