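"""Classification performance reports: confusion matrix, per-class
precision/recall/F1, weighted and macro F-measure, misclassification
profiles.

The weighted F-measure — the headline metric under heavy class imbalance —
is the support-weighted mean of per-class F1; macro F is the plain mean.
Zero-denominator cases (a class never predicted, or with no true samples)
score 0 and are flagged in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm


@dataclass
class ClassificationReport:
    labels: list[str]
    confusion: np.ndarray  # rows = true class, columns = predicted
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_f: float
    macro_f: float
    zero_division_flags: np.ndarray  # per-class: any P/R/F denominator vanished

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.labels,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
                "zero_division": self.zero_division_flags,
            }
        )


def confusion_matrix(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    label_order: Sequence[str],
) -> np.ndarray:
    """Entry (i, j) counts samples of true class i predicted as class j."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label lists differ in length")
    known = set(label_order)
    bad = [l for l in list(true_labels) + list(pred_labels) if l not in known]
    if bad:
        raise ValueError(f"labels outside vocabulary: {sorted(set(bad))[:5]}")
    return _skm.confusion_matrix(true_labels, pred_labels, labels=list(label_order))


def per_class_metrics(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision, recall and F1 per class from a square confusion matrix.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``F1 = 2PR/(P+R)``; any vanishing denominator yields 0.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(confusion).astype(float)
    pred_totals = confusion.sum(axis=0).astype(float)
    true_totals = confusion.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(true_totals > 0, tp / true_totals, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return precision, recall, f1


def aggregate_f(
    f1: Sequence[float], support: Sequence[int], mode: str = "weighted"
) -> float:
    """Support-weighted (``weighted``) or plain (``macro``) mean of per-class F1."""
    f1 = np.asarray(f1, dtype=float)
    support = np.asarray(support, dtype=float)
    if f1.shape != support.shape:
        raise ValueError("f1 and support lengths differ")
    if mode == "weighted":
        total = support.sum()
        if total == 0:
            raise ValueError("total support is zero")
        return float(np.sum(support * f1) / total)
    if mode == "macro":
        return float(np.mean(f1))
    raise ValueError(f"unknown mode {mode!r}")


def misclassification_profile(
    confusion: np.ndarray, class_index: int, labels: Sequence[str]
) -> list[tuple[str, float]]:
    """Off-diagonal rates for one true class, normalized by support, descending."""
    row = np.asarray(confusion)[class_index].astype(float)
    support = row.sum()
    if support == 0:
        return []
    pairs = [
        (labels[j], row[j] / support)
        for j in range(len(row))
        if j != class_index and row[j] > 0
    ]
    return sorted(pairs, key=lambda t: (-t[1], t[0]))


def evaluate(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    label_order: Sequence[str],
) -> ClassificationReport:
    """Full report from true/predicted label lists."""
    conf = confusion_matrix(true_labels, pred_labels, label_order)
    precision, recall, f1 = per_class_metrics(conf)
    support = conf.sum(axis=1)
    flags = (conf.sum(axis=0) == 0) | (support == 0) | ((precision + recall) == 0)
    return ClassificationReport(
        labels=list(label_order),
        confusion=conf,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        weighted_f=aggregate_f(f1, support, "weighted"),
        macro_f=aggregate_f(f1, support, "macro"),
        zero_division_flags=flags,
    )


def write_report(report: ClassificationReport, outdir: str | Path) -> None:
    """Emit confusion.tsv, per_class.tsv and summary.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.confusion, index=report.labels, columns=report.labels).to_csv(
        outdir / "confusion.tsv", sep="\t", index_label="true_class"
    )
    report.per_class_frame().to_csv(outdir / "per_class.tsv", sep="\t", index=False)
    summary = {
        "weighted_f": report.weighted_f,
        "macro_f": report.macro_f,
        "n_samples": int(report.confusion.sum()),
        "accuracy": float(np.trace(report.confusion) / max(report.confusion.sum(), 1)),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
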