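"""Evaluation suite: confusion-based weighted classification metrics, paired
effect sizes over per-seed results, and micro-averaged ROC/AUC.

Conventions: precision/recall/F1 define 0/0 as 0; accuracy is the standard
correct-over-total ratio; weighted averages use class support; dispersion
over seeds elsewhere in the package uses the population form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionSummary", "ClassificationReport", "EffectSizeReport", "RocSummary",
    "confusion", "classification_metrics", "cohens_d_paired", "rank_biserial",
    "micro_roc_auc",
]


@dataclass
class ConfusionSummary:
    """One-vs-rest counts per class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def n_samples(self) -> int:
        return int(self.support.sum())


def confusion(y_true, y_pred, n_classes: int) -> ConfusionSummary:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for y in (y_true, y_pred):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError("label outside 0..n_classes-1")
    n = y_true.size
    cm = np.zeros((n_classes, n_classes), int)
    np.add.at(cm, (y_true, y_pred), 1)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return ConfusionSummary(tp, fp, fn, tn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


@dataclass
class ClassificationReport:
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    macro_f1: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in
                ("accuracy", "weighted_precision", "weighted_recall",
                 "weighted_f1", "macro_f1")}


def classification_metrics(cs: ConfusionSummary) -> ClassificationReport:
    total = cs.n_samples
    if total == 0:
        raise ValueError("empty confusion summary")
    prec = _safe_div(cs.tp, cs.tp + cs.fp)
    rec = _safe_div(cs.tp, cs.tp + cs.fn)
    f1 = _safe_div(2 * prec * rec, prec + rec)
    support = cs.support
    wsum = support.sum()
    return ClassificationReport(
        accuracy=float(cs.tp.sum() / total),
        weighted_precision=float((prec * support).sum() / wsum),
        weighted_recall=float((rec * support).sum() / wsum),
        weighted_f1=float((f1 * support).sum() / wsum),
        macro_f1=float(f1.mean()),
        per_class_precision=prec, per_class_recall=rec, per_class_f1=f1,
    )


@dataclass
class EffectSizeReport:
    cohen_d: float
    rank_biserial: float
    n_pairs: int


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean difference over the sample (n-1) standard
    deviation of the differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.size < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pairs: zero spread in the differences")
    return float(d.mean() / sd)


def rank_biserial(x, y) -> float:
    """Matched-pairs rank-biserial correlation (W+ - W-)/(W+ + W-) over
    signed ranks of the nonzero paired differences; zero differences are
    dropped, ties receive average ranks."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


@dataclass
class RocSummary:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def micro_roc_auc(scores, y_true) -> RocSummary:
    """Micro-averaged one-vs-rest ROC: every (sample, class) pair becomes a
    binary decision, pooled into one curve; AUC by trapezoidal integration."""
    scores = np.asarray(scores, float)
    y_true = np.asarray(y_true)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise ValueError("scores must be (n_samples, n_classes)")
    n, C = scores.shape
    if y_true.min() < 0 or y_true.max() >= C:
        raise ValueError("label outside score-matrix width")
    onehot = np.eye(C, dtype=int)[y_true].ravel()
    flat = scores.ravel()
    fpr, tpr, _ = roc_curve(onehot, flat)
    auc = float(np.trapezoid(tpr, fpr))
    return RocSummary(fpr, tpr, auc)
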