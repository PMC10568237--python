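"""Confusion counts and the four summary statistics, AFIB-positive.

Accuracy, precision, recall and F1 are reported as percentages. When a
denominator is zero (e.g. an all-negative dataset has no positives, so
recall is undefined) the statistic is ``None`` with a warning, never a
silent zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @classmethod
    def from_labels(
        cls, y_true: Iterable, y_pred: Iterable, positive="AFIB"
    ) -> "ConfusionCounts":
        t = np.asarray(list(y_true)) == positive
        p = np.asarray(list(y_pred)) == positive
        if t.size != p.size:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )


def score(counts: ConfusionCounts) -> dict[str, Optional[float]]:
    """Accuracy, precision, recall, F1 as percentages.

    Undefined branches (zero denominators) return ``None`` with a warning.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    prec = rec = f1 = None
    if counts.tp + counts.fp > 0:
        prec = 100.0 * counts.tp / (counts.tp + counts.fp)
    else:
        warnings.warn("precision undefined: no positive predictions")
    if counts.tp + counts.fn > 0:
        rec = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        warnings.warn("recall undefined: no positive cases")
    if prec is not None and rec is not None and prec + rec > 0:
        f1 = 2.0 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def format_report(counts: ConfusionCounts, decimals: int = 2) -> dict:
    """Counts plus statistics rounded for reporting."""
    stats = {
        k: (None if v is None else round(v, decimals))
        for k, v in score(counts).items()
    }
    return {
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        **stats,
    }


def render_confusion(counts: ConfusionCounts) -> str:
    """Plain-text confusion matrix, AFIB as the positive class."""
    w = max(len(str(v)) for v in (counts.tp, counts.fp, counts.tn, counts.fn))
    w = max(w, 4)
    return "\n".join(
        [
            f"{'':12s}  {'pred AFIB':>{w + 6}s}  {'pred NSR':>{w + 6}s}",
            f"{'true AFIB':12s}  {counts.tp:>{w + 6}d}  {counts.fn:>{w + 6}d}",
            f"{'true NSR':12s}  {counts.fp:>{w + 6}d}  {counts.tn:>{w + 6}d}",
        ]
    )
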