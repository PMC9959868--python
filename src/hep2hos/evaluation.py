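"""Confusion matrix, per-class correct-classification rate (CCR), mean
class accuracy (MCA), and the positive/intermediate level report.

CCR_n is implemented as per-class recall, correct_n / M_n with M_n the
number of test images of class n, and MCA as the unweighted mean of the
per-class rates — the contest metric for HEp-2 cell classification.
Printed rates use round-half-up to two decimals; full precision is kept
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "ccr_per_class",
    "mca",
    "level_report",
    "evaluate",
    "round_rate",
]


def round_rate(fraction: float, decimals: int = 2) -> float:
    """100 * fraction rounded half-up to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float(
        Decimal(repr(100 * float(fraction))).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i+1 predicted j+1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    ccr_per_class: np.ndarray  # NaN where a class had no test samples
    mca: float
    per_level_table: Optional[pd.DataFrame] = None

    def to_text(self, class_names: Optional[Sequence[str]] = None) -> str:
        k = self.confusion.k
        names = list(class_names) if class_names else [f"class_{i+1}" for i in range(k)]
        lines = ["class                 images   CCR%"]
        totals = self.confusion.counts.sum(axis=1)
        correct = np.diag(self.confusion.counts)
        for i in range(k):
            rate = "   n/a" if totals[i] == 0 else f"{round_rate(correct[i]/totals[i]):6.2f}"
            lines.append(f"{names[i]:<20} {totals[i]:7d} {rate}")
        lines.append(f"{'MCA':<20} {totals.sum():7d} {round_rate(self.mca):6.2f}")
        if self.per_level_table is not None:
            lines.append("")
            lines.append(self.per_level_table.to_string(index=False))
        return "\n".join(lines)


def confusion(y_true, y_pred, k: int) -> ConfusionMatrix:
    """k x k confusion matrix for 1-based labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 1 or arr.max() > k):
            raise ValueError(f"{name} labels must lie in 1..{k}")
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(1, k + 1))
    return ConfusionMatrix(cm)


def ccr_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class correct-classification rate; NaN for empty classes."""
    totals = cm.counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} class(es) have no test samples; "
            "their CCR is undefined and excluded from the MCA",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.diag(cm.counts) / totals
    rates[empty] = np.nan
    return rates


def mca(rates) -> float:
    """Unweighted mean of the defined per-class rates."""
    rates = np.asarray(rates, dtype=float)
    defined = rates[np.isfinite(rates)]
    if defined.size == 0:
        raise ValueError("no defined per-class rates")
    return float(defined.mean())


def level_report(
    y_true,
    y_pred,
    levels,
    class_names: Optional[Sequence[str]] = None,
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Per-class, per-intensity-level accuracy table plus overall rows.

    ``levels`` tags each sample ``"positive"`` or ``"intermediate"``.
    Rates are 100 * correct / total rounded half-up to two decimals;
    classes with no samples at a level are omitted for that level.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    levels = np.asarray(levels)
    if not (y_true.shape == y_pred.shape == levels.shape):
        raise ValueError("y_true, y_pred and levels must have equal length")
    bad = set(np.unique(levels)) - {"positive", "intermediate"}
    if bad:
        raise ValueError(f"unknown level tag(s): {sorted(bad)}")
    kk = k or int(y_true.max(initial=1))
    names = list(class_names) if class_names else [f"class_{i+1}" for i in range(kk)]

    rows = []
    for level in ("positive", "intermediate"):
        sel = levels == level
        for c in range(1, kk + 1):
            in_class = sel & (y_true == c)
            total = int(in_class.sum())
            if total == 0:
                continue
            correct = int((y_pred[in_class] == c).sum())
            rows.append(
                {
                    "class": names[c - 1],
                    "level": level,
                    "correct": correct,
                    "total": total,
                    "rate_pct": round_rate(correct / total),
                }
            )
        total = int(sel.sum())
        if total:
            correct = int((y_pred[sel] == y_true[sel]).sum())
            rows.append(
                {
                    "class": "overall",
                    "level": level,
                    "correct": correct,
                    "total": total,
                    "rate_pct": round_rate(correct / total),
                }
            )
    return pd.DataFrame(rows, columns=["class", "level", "correct", "total", "rate_pct"])


def evaluate(
    y_true,
    y_pred,
    k: int,
    levels=None,
    class_names: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Full evaluation: confusion matrix, CCR per class, MCA and, when
    intensity-level tags are supplied, the per-level table."""
    cm = confusion(y_true, y_pred, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rates = ccr_per_class(cm)
    table = None
    if levels is not None:
        table = level_report(y_true, y_pred, levels, class_names=class_names, k=k)
    return EvaluationReport(cm, rates, mca(rates), table)
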