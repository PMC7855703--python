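"""Confusion matrices and the metric arithmetic used to score the classifier.

Metrics here are orientation-explicit. A K x K confusion matrix is indexed by
two label streams (rows by the first, columns by the second); whether rows
mean "truth" and columns "prediction" is a reporting convention, so every
metric names the axis it normalizes over:

- ``overall_accuracy``: 100 x trace / total.
- ``macro_row_ratio``: unweighted mean over classes of diagonal / row total
  (macro precision when rows are predictions, macro recall when rows are
  truth).
- ``macro_col_ratio``: same with column totals.
- ``class_row_ratio`` / ``class_col_ratio``: the per-class versions.

All percentages are rounded half-up to one decimal, matching how such tables
are conventionally printed.

Three reference confusion matrices from a published evaluation of this
pipeline design (melanoma, triple-negative breast cancer, and mouse
neuroblastoma cohorts) ship as CSV fixtures; see ``data/README.md`` for two
documented printing inconsistencies in their accompanying summary figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "overall_accuracy",
    "macro_row_ratio",
    "macro_col_ratio",
    "class_row_ratio",
    "class_col_ratio",
    "load_reference_table",
    "REFERENCE_TABLES",
]

#: packaged reference fixtures: name -> CSV resource
REFERENCE_TABLES = {
    "melanoma": "table4_melanoma.csv",
    "tnbc": "table5_tnbc.csv",
    "neuroblastoma": "table6_neuroblastoma.csv",
}


def _round1(x: float) -> float:
    """Round half-up to one decimal on the percentage scale."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square count matrix over an ordered class list.

    Rows are indexed by the first label stream passed to :func:`confusion`,
    columns by the second; the class order is shared by both axes.
    """

    counts: np.ndarray
    class_names: List[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K matching class_names")
        if k < 2:
            raise ValueError("need at least 2 classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column class names must match")
        return cls(counts=df.to_numpy(), class_names=[str(c) for c in df.columns])


def confusion(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    """Tally co-occurrences: counts[i, j] = #positions with a=class_i, b=class_j."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        if a not in index or b not in index:
            raise ValueError(f"unknown label in pair ({a!r}, {b!r})")
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total, one decimal."""
    if cm.total == 0:
        raise ValueError("empty matrix")
    return _round1(100.0 * np.trace(cm.counts) / cm.total)


def macro_row_ratio(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class diagonal / row-total percentages."""
    rows = cm.counts.sum(axis=1)
    if np.any(rows == 0):
        bad = cm.class_names[int(np.argmin(rows))]
        raise ValueError(f"zero row total for class {bad!r}")
    return _round1(float(np.mean(100.0 * np.diag(cm.counts) / rows)))


def macro_col_ratio(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class diagonal / column-total percentages."""
    cols = cm.counts.sum(axis=0)
    if np.any(cols == 0):
        bad = cm.class_names[int(np.argmin(cols))]
        raise ValueError(f"zero column total for class {bad!r}")
    return _round1(float(np.mean(100.0 * np.diag(cm.counts) / cols)))


def class_row_ratio(cm: ConfusionMatrix, class_name: str) -> float:
    """Diagonal / row total for one class, as a one-decimal percentage."""
    i = cm.class_names.index(class_name)
    row = cm.counts[i].sum()
    if row == 0:
        raise ValueError(f"zero row total for class {class_name!r}")
    return _round1(100.0 * cm.counts[i, i] / row)


def class_col_ratio(cm: ConfusionMatrix, class_name: str) -> float:
    """Diagonal / column total for one class, as a one-decimal percentage."""
    i = cm.class_names.index(class_name)
    col = cm.counts[:, i].sum()
    if col == 0:
        raise ValueError(f"zero column total for class {class_name!r}")
    return _round1(100.0 * cm.counts[i, i] / col)


def load_reference_table(name: str) -> ConfusionMatrix:
    """Load one of the packaged reference confusion matrices.

    ``name`` is a key of :data:`REFERENCE_TABLES` ("melanoma", "tnbc",
    "neuroblastoma") or a fixture filename.
    """
    fname = REFERENCE_TABLES.get(name, name)
    ref = resources.files("histomap").joinpath("data", fname)
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_csv(path)
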