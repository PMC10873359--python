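"""Evaluation: patch-level validation metrics and slide-level
leave-one-patient-out (LOPO) retrieval evaluation.

Patch-level metrics treat "abnormal" as the positive class (both classes are
reported).  Slide-level evaluation queries each indexed slide against the index
with all slides of the same patient excluded, takes the top-1 label and
majority votes among the top-3/top-5, and aggregates per-class
precision/recall/F1, a confusion matrix, the support-weighted F1, and the mean
number of selected patches per slide.  F1 with a zero denominator is defined
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from normatlas.search import WSIIndex, predict_label, query_index
from normatlas.slide_patching import ABNORMAL, NORMAL


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # rows = truth, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        L = len(self.labels)
        if self.counts.shape != (L, L):
            raise ValueError(f"counts must be {L}x{L}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "counts": self.counts.tolist()}


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    weighted_f1: float
    confusion: ConfusionMatrix
    mean_patches_per_wsi: float = float("nan")
    reduction_vs_baseline: float | None = None

    def to_dict(self) -> dict:
        return {
            "per_class": {
                lab: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                }
                for lab, m in sorted(self.per_class.items())
            },
            "weighted_f1": self.weighted_f1,
            "confusion": self.confusion.to_dict(),
            "mean_patches_per_wsi": self.mean_patches_per_wsi,
            "reduction_vs_baseline": self.reduction_vs_baseline,
        }


def _report_from_pairs(
    truth: Sequence[str], predicted: Sequence[str], labels: list[str]
) -> EvalReport:
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predicted, labels=labels, zero_division=0
    )
    per_class = {
        lab: ClassMetrics(float(p), float(r), float(f), int(s))
        for lab, p, r, f, s in zip(labels, prec, rec, f1, support)
    }
    total = support.sum()
    weighted = float(np.dot(f1, support) / total) if total else 0.0
    cm = ConfusionMatrix(labels=labels, counts=_sk_confusion(truth, predicted, labels=labels))
    return EvalReport(per_class=per_class, weighted_f1=weighted, confusion=cm)


def patch_level_eval(truth: Sequence[str], predicted: Sequence[str]) -> EvalReport:
    """Binary patch-classification metrics against annotation-derived labels."""
    if len(truth) == 0 or len(truth) != len(predicted):
        raise ValueError(
            f"truth and predicted must be equal-length and non-empty "
            f"({len(truth)} vs {len(predicted)})"
        )
    return _report_from_pairs(truth, predicted, [NORMAL, ABNORMAL])


def lopo_evaluate(
    index: WSIIndex, k_values: Iterable[int] = (1, 3, 5)
) -> dict[int, EvalReport]:
    """Leave-one-patient-out retrieval evaluation over an index.

    Each indexed slide queries the index with its own patient excluded.  A
    slide whose selection was entirely pruned (no vectors) is predicted
    "normal" at every k without search.
    """
    k_values = sorted(set(k_values))
    if len(index.patients) < 2:
        raise ValueError("LOPO evaluation requires at least 2 patients")
    truths: list[str] = []
    preds: dict[int, list[str]] = {k: [] for k in k_values}
    for entry in index.entries:
        truths.append(entry.label)
        if entry.n_patches == 0:
            for k in k_values:
                preds[k].append(predict_label(None, k))
            continue
        result = query_index(
            index, entry, exclude_patient=entry.patient_id, k_values=k_values
        )
        for k in k_values:
            preds[k].append(result.predictions[k])
    labels = sorted(set(truths) | {lab for k in k_values for lab in preds[k]})
    mean_patches = float(np.mean([e.n_patches for e in index.entries]))
    reports = {}
    for k in k_values:
        report = _report_from_pairs(truths, preds[k], labels)
        report.mean_patches_per_wsi = mean_patches
        reports[k] = report
    return reports


def reduction_report(baseline: EvalReport, pruned: EvalReport) -> float:
    """Relative drop in mean selected patches per slide vs the no-atlas baseline."""
    if not baseline.mean_patches_per_wsi or baseline.mean_patches_per_wsi <= 0:
        raise ValueError("baseline mean patches per WSI must be positive")
    reduction = 1.0 - pruned.mean_patches_per_wsi / baseline.mean_patches_per_wsi
    pruned.reduction_vs_baseline = reduction
    return reduction
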