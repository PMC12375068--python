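"""Classification metrics from a multiclass confusion matrix.

Per-class values are computed one-vs-rest from the per-class TP/FP/TN/FN
decomposition and macro-averaged (unweighted mean over classes).  A ratio
with a zero denominator is reported as an explicit undefined marker (NaN)
and excluded from the macro average; the number of excluded classes is
recorded per metric.  The Matthews correlation coefficient uses the standard
multiclass generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion",
           "classification_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix indexed (true class, predicted class)."""
    counts: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any() or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("confusion matrix entries must be counts")
        object.__setattr__(self, "counts", m)

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> Dict[str, np.ndarray]:
        """One-vs-rest TP/FP/TN/FN per class; each sums to the total count."""
        m = self.counts
        tp = np.diag(m).astype(np.int64)
        fp = m.sum(axis=0) - tp
        fn = m.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def confusion(y_true: Sequence[int], y_pred: Sequence[int],
              num_classes: int) -> ConfusionMatrix:
    """Count (true, predicted) label pairs."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size and (t.min() < 0 or p.min() < 0 or t.max() >= num_classes
                   or p.max() >= num_classes):
        raise ValueError("label out of range")
    m = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return ConfusionMatrix(m)


@dataclass
class MetricReport:
    """Macro-averaged metric record with per-class detail.

    ``undefined_counts`` records, per metric, how many classes were excluded
    from the macro average because of a 0/0 denominator.
    """
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    f1: float
    mcc: float
    per_class: Dict[str, np.ndarray] = field(default_factory=dict)
    undefined_counts: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in
                ("accuracy", "precision", "sensitivity", "specificity",
                 "fpr", "fnr", "f1", "mcc")}

    def to_tsv(self) -> str:
        lines = ["metric\tvalue\tundefined_classes"]
        for k, v in self.as_dict().items():
            lines.append(f"{k}\t{v:.6f}\t{self.undefined_counts.get(k, 0)}")
        return "\n".join(lines)


def _ratio(num, den):
    """Elementwise num/den with NaN where the denominator is zero."""
    num = num.astype(np.float64)
    den = den.astype(np.float64)
    out = np.full_like(num, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _macro(values):
    ok = ~np.isnan(values)
    mean = float(values[ok].mean()) if ok.any() else float("nan")
    return mean, int((~ok).sum())


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Standard multiclass Matthews correlation coefficient."""
    m = cm.counts.astype(np.float64)
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)   # true-class totals
    p = m.sum(axis=0)   # predicted-class totals
    num = c * s - (p * t).sum()
    den = np.sqrt((s ** 2 - (p ** 2).sum()) * (s ** 2 - (t ** 2).sum()))
    return float(num / den) if den > 0 else float("nan")


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, macro precision/sensitivity/specificity/FPR/FNR/F1, and MCC."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    d = cm.per_class()
    tp, fp, tn, fn = d["tp"], d["fp"], d["tn"], d["fn"]

    per = {
        "precision": _ratio(tp, tp + fp),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "fpr": _ratio(fp, fp + tn),
        "fnr": _ratio(fn, fn + tp),
    }
    # harmonic mean of precision and recall, in the 0/0-robust 2TP form
    per["f1"] = _ratio(2 * tp, 2 * tp + fp + fn)

    macro, undef = {}, {}
    for k, v in per.items():
        macro[k], undef[k] = _macro(v)

    return MetricReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=macro["precision"],
        sensitivity=macro["sensitivity"],
        specificity=macro["specificity"],
        fpr=macro["fpr"],
        fnr=macro["fnr"],
        f1=macro["f1"],
        mcc=multiclass_mcc(cm),
        per_class=per,
        undefined_counts=undef,
    )
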