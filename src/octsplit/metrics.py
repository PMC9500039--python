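"""Confusion-matrix-derived multiclass evaluation metrics.

Implements the multiclass Matthews Correlation Coefficient (the Rk
statistic), one-vs-rest per-class accuracy/precision/recall/F1 in the
Sokolova formulation, rank-based one-vs-rest ROC AUC, and the pooled
``mean ± std`` aggregation over trained models and classes used to
summarise repeated cross-validation runs.

All scalar metrics derive from a single ``K × K`` integer confusion matrix
with rows = true class and columns = predicted class, in the dataset's
``class_set`` order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) non-negative ints; rows true, cols predicted
    class_set: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if len(self.class_set) != self.counts.shape[0]:
            raise ValueError("class_set length must match matrix dimension")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels, predicted_labels, class_set) -> ConfusionMatrix:
    """Count matrix ``counts[i, j]`` = records of true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    if not true_labels:
        raise ValueError("cannot build a confusion matrix from empty label lists")
    lookup = {c: i for i, c in enumerate(class_set)}
    k = len(class_set)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lookup:
            raise ValueError(f"true label {t!r} not in class_set {list(class_set)}")
        if p not in lookup:
            raise ValueError(f"predicted label {p!r} not in class_set {list(class_set)}")
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(counts=counts, class_set=list(class_set))


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews Correlation Coefficient (Rk statistic).

    With s = total count, c = trace, t_k = row sums, p_k = column sums::

        MCC = (c*s - sum_k t_k p_k) / sqrt((s^2 - sum_k p_k^2)(s^2 - sum_k t_k^2))

    Returns 0.0 when either denominator factor vanishes (e.g. all
    predictions in a single class), the convention under which chance-level
    degenerate classifiers score zero rather than NaN.
    """
    counts = cm.counts.astype(np.float64)
    s = counts.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(counts)
    t = counts.sum(axis=1)
    p = counts.sum(axis=0)
    cov_tp = c * s - t @ p
    cov_pp = s * s - p @ p
    cov_tt = s * s - t @ t
    if cov_pp == 0 or cov_tt == 0:
        return 0.0
    return float(cov_tp / np.sqrt(cov_pp * cov_tt))


@dataclass
class MetricsReport:
    """Scalar metrics for one evaluated model.

    Per-class vectors follow ``class_set`` order; macro values are unweighted
    class means. ``accuracy_overall`` is trace/total (micro accuracy);
    ``accuracy`` per class is the one-vs-rest (TP+TN)/s Sokolova form.
    """

    class_set: list[str]
    mcc: float
    accuracy_overall: float
    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    auc: np.ndarray = field(default=None)
    macro: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat dict (one CSV row per trained model)."""
        row = {"mcc": self.mcc, "accuracy_overall": self.accuracy_overall}
        for name in ("accuracy", "precision", "recall", "f1", "auc"):
            vec = getattr(self, name)
            if vec is None:
                continue
            for cls, v in zip(self.class_set, vec):
                row[f"{name}_{cls}"] = float(v)
            row[f"{name}_macro"] = self.macro.get(name, float(np.nanmean(vec)))
        return row


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy, precision, recall and F1 per class, plus macro means.

    Zero-denominator convention: precision/recall are 0 when undefined; F1 is
    0 when precision + recall = 0.
    """
    counts = cm.counts.astype(np.float64)
    s = counts.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = s - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    accuracy = (tp + tn) / s
    report = MetricsReport(
        class_set=list(cm.class_set),
        mcc=mcc(cm),
        accuracy_overall=float(tp.sum() / s),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
    )
    report.macro = {
        "accuracy": float(accuracy.mean()),
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }
    return report


def roc_auc(true_labels, probability_rows, class_set) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class via the Mann-Whitney rank formulation.

    For class k the score is the predicted probability of k and the positive
    indicator is ``true == k``; ties are handled by midranks, so a constant
    score gives AUC 0.5. Classes absent from the true labels get NaN and are
    excluded from the macro mean with a warning.

    Returns ``(per_class_auc, macro_auc)``.
    """
    probs = np.asarray(probability_rows, dtype=np.float64)
    true_labels = np.asarray(list(true_labels))
    if probs.ndim != 2 or probs.shape[1] != len(class_set):
        raise ValueError("probability rows must be (n, K) aligned with class_set")
    if probs.shape[0] != len(true_labels):
        raise ValueError("labels and probability rows differ in length")
    aucs = np.full(len(class_set), np.nan)
    for k, cls in enumerate(class_set):
        pos = true_labels == cls
        n_pos = int(pos.sum())
        n_neg = len(pos) - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(probs[:, k])  # midranks
        # Mann-Whitney U of positives over negatives
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[k] = u / (n_pos * n_neg)
    if np.isnan(aucs).any():
        missing = [c for c, a in zip(class_set, aucs) if np.isnan(a)]
        warnings.warn(
            f"AUC undefined for classes absent from the truth: {missing}; "
            "excluded from the macro mean",
            stacklevel=2,
        )
    macro = float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan")
    return aucs, macro


def evaluate(true_labels, probability_rows, class_set) -> MetricsReport:
    """Full report (CM metrics + AUC) from probabilities; argmax gives hard labels."""
    probs = np.asarray(probability_rows, dtype=np.float64)
    hard = [class_set[i] for i in probs.argmax(axis=1)]
    cm = confusion_matrix(true_labels, hard, class_set)
    report = per_class_metrics(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aucs, macro_auc = roc_auc(true_labels, probs, class_set)
    report.auc = aucs
    report.macro["auc"] = macro_auc
    return report


def aggregate_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """Pooled ``mean ± std`` over models and classes.

    Class-resolved metrics (accuracy, precision, recall, F1, AUC) pool all
    (model, class) values before taking the mean and sample standard
    deviation (n-1 denominator; 0 when a single value). MCC and overall
    accuracy pool one value per model.
    """
    if not reports:
        raise ValueError("aggregate_reports needs at least one report")

    def _mean_std(values: np.ndarray) -> tuple[float, float]:
        values = values[~np.isnan(values)]
        std = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        return float(values.mean()), std

    rows = []
    for name in ("mcc", "accuracy_overall"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        m, s = _mean_std(vals)
        rows.append({"metric": name, "mean": m, "std": s, "n": len(vals)})
    for name in ("auc", "f1", "accuracy", "precision", "recall"):
        pooled = []
        for r in reports:
            vec = getattr(r, name)
            if vec is not None:
                pooled.extend(np.asarray(vec, dtype=float))
        if pooled:
            vals = np.array(pooled)
            m, s = _mean_std(vals)
            rows.append({"metric": name, "mean": m, "std": s, "n": int(np.isfinite(vals).sum())})
    return pd.DataFrame(rows).set_index("metric")
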