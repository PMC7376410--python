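"""Segmentation evaluation: confusion counts, DSC, sensitivity, specificity.

Conventions for a binary tumor/background map: TP is a pixel predicted tumor
that truly is tumor, FP predicted tumor but background, TN predicted and
truly background, FN predicted background but truly tumor.  From the counts,

    DSC  = 2·TP / (FP + 2·TP + FN)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)

Degenerate denominators follow common benchmark practice (logged when hit):
an empty truth *and* empty prediction scores DSC 1.0; sensitivity/specificity
with an empty positive/negative class are undefined and reported as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import LabelMap, LabelScheme

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts", "dsc",
           "sensitivity", "specificity", "case_metrics", "cohort_report",
           "relative_improvement"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Cohort-level summary plus (optionally) the per-case rows it averages."""

    dsc: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    n_cases: int = 1
    per_case: Optional[List[Tuple]] = None  # (case_id, dsc, sens, spec)


def _as_binary(m: LabelMap, name: str) -> np.ndarray:
    if m.scheme is not LabelScheme.BINARY:
        raise ValueError(f"{name} must be a BINARY label map, got {m.scheme.value}")
    return m.data


def confusion_counts(pred: LabelMap, truth: LabelMap) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/TN/FN between two binary maps."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2·TP/(FP + 2·TP + FN); empty/empty → 1.0."""
    denom = counts.fp + 2 * counts.tp + counts.fn
    if denom == 0:
        logger.info("DSC on empty truth and empty prediction: defined as 1.0")
        return 1.0
    return 2.0 * counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> Optional[float]:
    """True-positive rate TP/(TP + FN); undefined (None) when truth is empty."""
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.info("sensitivity undefined: no positive pixels in truth")
        return None
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> Optional[float]:
    """True-negative rate TN/(TN + FP); undefined (None) when truth has no background."""
    denom = counts.tn + counts.fp
    if denom == 0:
        logger.info("specificity undefined: no negative pixels in truth")
        return None
    return counts.tn / denom


def case_metrics(pred: LabelMap, truth: LabelMap, case_id: str = "") -> Tuple:
    """Convenience: (case_id, dsc, sensitivity, specificity) for one case."""
    c = confusion_counts(pred, truth)
    return (case_id, dsc(c), sensitivity(c), specificity(c))


def cohort_report(per_case: Sequence[Tuple]) -> MetricReport:
    """Unweighted means of per-case (case_id, dsc, sens, spec) rows.

    Undefined (None) entries are excluded from their mean; the exclusion
    count is logged.  Per-case rows are retained on the report.
    """
    rows = list(per_case)
    if not rows:
        raise ValueError("cohort_report requires at least one case")

    def _mean(i: int) -> Optional[float]:
        vals = [r[i] for r in rows if r[i] is not None]
        n_missing = len(rows) - len(vals)
        if n_missing:
            logger.info("cohort mean (column %d): %d undefined case(s) excluded", i, n_missing)
        return float(np.mean(vals)) if vals else None

    return MetricReport(dsc=_mean(1), sensitivity=_mean(2), specificity=_mean(3),
                        n_cases=len(rows), per_case=rows)


def relative_improvement(new: float, baseline: float) -> float:
    """Relative percent change 100·(new − baseline)/baseline, one decimal place."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    return round(100.0 * (new - baseline) / baseline, 1)
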