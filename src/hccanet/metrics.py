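"""Evaluation metrics: confusion matrix, per-class precision/recall/F1,
accuracy, and one-vs-rest ROC AUC with macro averaging.

Per class c (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2·P·R/(P+R); accuracy = (TP+TN)/(TP+TN+FP+FN) overall, which on
single-label data equals trace/total.  Zero-denominator rates are
reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["MetricsReport", "compute_metrics", "roc_auc_ovr"]


@dataclass
class MetricsReport:
    labels: list
    confusion: np.ndarray                   # rows = true, cols = predicted
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    auc: dict = field(default_factory=dict)       # per-class one-vs-rest
    macro_auc: float | None = None
    zero_division_flags: list = field(default_factory=list)
    undefined_auc: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "confusion": self.confusion.tolist(),
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "accuracy": self.accuracy,
            "auc": {str(k): v for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
            "zero_division_flags": [str(l) for l in self.zero_division_flags],
            "undefined_auc": [str(l) for l in self.undefined_auc],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.labels, columns=self.labels)


def compute_metrics(y_true, y_pred, labels=None) -> MetricsReport:
    """Confusion tally and the rate metrics above; rates only (no AUC)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    labels = list(labels)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    total = cm.sum()
    precision, recall, f1 = {}, {}, {}
    flags = []

    def _rate(num: float, den: float, label, what: str) -> float:
        if den == 0:
            flags.append((label, what))
            return 0.0
        return num / den

    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = _rate(tp, tp + fp, lab, "precision")
        r = _rate(tp, tp + fn, lab, "recall")
        precision[lab] = p
        recall[lab] = r
        f1[lab] = _rate(2 * p * r, p + r, lab, "f1")
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return MetricsReport(
        labels=labels, confusion=cm, precision=precision, recall=recall, f1=f1,
        accuracy=accuracy, zero_division_flags=[l for l, _ in flags],
    )


def roc_auc_ovr(y_true, class_scores, labels=None) -> tuple[dict, float]:
    """One-vs-rest AUC per class (midrank tie handling) and the macro mean.

    ``class_scores`` is (n, K) with columns in label order.  A class absent
    from ``y_true`` has no defined AUC: it is reported as nan and excluded
    from the macro average.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(class_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("class_scores must be (n_samples, n_classes)")
    if labels is None:
        labels = sorted(set(y_true.tolist()))
    labels = list(labels)
    if scores.shape[1] != len(labels):
        raise ValueError(f"{scores.shape[1]} score columns for {len(labels)} labels")
    aucs: dict = {}
    undefined = []
    for k, lab in enumerate(labels):
        pos = y_true == lab
        if pos.all() or not pos.any():
            aucs[lab] = float("nan")
            undefined.append(lab)
            continue
        # Mann-Whitney rank statistic with midrank ties:
        # AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg)
        ranks = rankdata(scores[:, k])
        n_pos = int(pos.sum())
        n_neg = len(pos) - n_pos
        r_pos = float(ranks[pos].sum())
        aucs[lab] = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    defined = [v for v in aucs.values() if not np.isnan(v)]
    macro = float(np.mean(defined)) if defined else float("nan")
    return aucs, macro


def attach_auc(report: MetricsReport, y_true, class_scores) -> MetricsReport:
    aucs, macro = roc_auc_ovr(y_true, class_scores, labels=report.labels)
    report.auc = aucs
    report.macro_auc = macro
    report.undefined_auc = [l for l, v in aucs.items() if np.isnan(v)]
    return report
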