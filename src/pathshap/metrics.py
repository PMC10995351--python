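"""Confusion matrices with per-category precision/accuracy conventions.

Rows of the confusion matrix are true categories, columns predictions.
*Local precision* of a category is its diagonal cell over the column
total (correct predictions over all predictions of that category);
*local accuracy* is the diagonal cell over the row total (correct
predictions over trials of that category); *global accuracy* is the
trace over the grand total.  Percentages are reported to one decimal
place with half-up rounding.  Undefined ratios (an empty row or column)
surface as ``None`` sentinels, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .synthetic import CATEGORIES


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (n_cat, n_cat) ints, rows = true, cols = predicted
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self):
        c = np.asarray(self.counts)
        n = len(self.categories)
        if c.shape != (n, n) or (c < 0).any():
            raise ValueError("counts must be a non-negative square matrix")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def _index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise ValueError(f"unknown category: {category!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.categories)
        )


def confusion(
    y_true, y_pred, categories: tuple[str, ...] = CATEGORIES
) -> ConfusionMatrix:
    """Tally a confusion matrix from paired label sequences."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences have different lengths")
    bad = (set(y_true) | set(y_pred)) - set(categories)
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    if not y_true:
        counts = np.zeros((len(categories), len(categories)), dtype=int)
    else:
        counts = _sk_confusion(y_true, y_pred, labels=list(categories))
    return ConfusionMatrix(counts=counts, categories=categories)


def local_precision(cm: ConfusionMatrix, category: str) -> float | None:
    """Diagonal over column total; ``None`` when the column is empty."""
    k = cm._index(category)
    col = cm.column_totals[k]
    if col == 0:
        return None
    return float(cm.counts[k, k] / col)


def local_accuracy(cm: ConfusionMatrix, category: str) -> float | None:
    """Diagonal over row total; ``None`` when the row is empty."""
    k = cm._index(category)
    row = cm.row_totals[k]
    if row == 0:
        return None
    return float(cm.counts[k, k] / row)


def global_accuracy(cm: ConfusionMatrix) -> float | None:
    """Trace over grand total; ``None`` for an empty matrix."""
    if cm.grand_total == 0:
        return None
    return float(cm.trace / cm.grand_total)


def percent(fraction: float | None, decimals: int = 1) -> float | None:
    """Fraction -> percentage with half-up rounding (54.6 style)."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(
        Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP)
    )


def report_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Panel layout: counts, totals, precision and accuracy rows (percent)."""
    prec = [percent(local_precision(cm, c)) for c in cm.categories]
    acc = [percent(local_accuracy(cm, c)) for c in cm.categories]
    rows = [list(r) + [t] for r, t in zip(cm.counts, cm.row_totals)]
    rows.append(list(cm.column_totals) + [cm.grand_total])
    rows.append(prec + [None])
    rows.append(acc + [percent(global_accuracy(cm))])
    return pd.DataFrame(
        rows,
        index=list(cm.categories) + ["Total", "Precision", "Accuracy"],
        columns=list(cm.categories) + ["Total"],
        dtype=object,
    )


#: Published benchmark panel (best dense network) from the brand-perception
#: study this pipeline models; the printed counts are the input for
#: regression-checking the metric arithmetic.  Rows/columns in BP, BI, O, P
#: order; rows are true categories.
BENCHMARK_BEST_NETWORK = ConfusionMatrix(
    counts=np.array(
        [
            [104, 82, 54, 40],
            [94, 108, 48, 30],
            [30, 43, 177, 30],
            [24, 12, 21, 222],
        ]
    ),
    categories=CATEGORIES,
)
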