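"""Confusion matrix and per-class sensitivity / positive predictivity.

Rows of the confusion matrix are true classes, columns are predicted
classes.  Per class, with TP the diagonal entry, FN the rest of the row
and FP the rest of the column:

    Se  = TP / (TP + FN) * 100%      (sensitivity / recall)
    Pp  = TP / (TP + FP) * 100%      (positive predictivity / precision)

Overall accuracy is the multiclass correct-over-total rate
``trace / total`` — equivalently the micro-averaged Se, which for a
single confusion matrix always equals the micro-averaged Pp.  A binary
per-class accuracy ``(TP + TN) / total`` is exposed as well.  Cells with
a zero denominator report 0% with a degeneracy flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[true, predicted] over an ordered class list."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        m = len(self.classes)
        if counts.shape != (m, m):
            raise ValueError(f"counts must be {m}x{m}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise ValueError(f"class {cls!r} not in {self.classes}") from None


@dataclass(frozen=True)
class ClassMetrics:
    """Sensitivity and positive predictivity (percent) of one class.

    ``degenerate_se`` / ``degenerate_pp`` flag a 0/0 cell that was
    reported as 0%.
    """

    se: float
    pp: float
    support: int
    degenerate_se: bool = False
    degenerate_pp: bool = False


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
) -> ConfusionMatrix:
    """Tally counts[a, b] = #{i : true_i = a, pred_i = b}."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    index = {c: j for j, c in enumerate(classes)}
    m = len(classes)
    counts = np.zeros((m, m), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"true label {t!r} not in classes")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in classes")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """Se and Pp (percent) of one class from the confusion matrix."""
    j = cm.index(cls)
    tp = int(cm.counts[j, j])
    fn = int(cm.counts[j, :].sum()) - tp
    fp = int(cm.counts[:, j].sum()) - tp
    degenerate_se = tp + fn == 0
    degenerate_pp = tp + fp == 0
    se = 0.0 if degenerate_se else 100.0 * tp / (tp + fn)
    pp = 0.0 if degenerate_pp else 100.0 * tp / (tp + fp)
    return ClassMetrics(
        se=se,
        pp=pp,
        support=tp + fn,
        degenerate_se=degenerate_se,
        degenerate_pp=degenerate_pp,
    )


def binary_class_accuracy(cm: ConfusionMatrix, cls: str) -> float:
    """One-vs-rest accuracy (TP + TN) / total * 100% for one class."""
    j = cm.index(cls)
    tp = int(cm.counts[j, j])
    fn = int(cm.counts[j, :].sum()) - tp
    fp = int(cm.counts[:, j].sum()) - tp
    tn = cm.total - tp - fn - fp
    return 100.0 * (tp + tn) / cm.total


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Multiclass accuracy trace/total as a percentage."""
    if cm.total < 1:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def metrics_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class Se/Pp/support plus a micro-averaged Total row."""
    rows = []
    for cls in cm.classes:
        met = class_metrics(cm, cls)
        rows.append(
            {"class": cls, "support": met.support, "se_pct": met.se, "pp_pct": met.pp}
        )
    acc = overall_accuracy(cm)
    rows.append({"class": "Total", "support": cm.total, "se_pct": acc, "pp_pct": acc})
    return pd.DataFrame(rows)


def confusion_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    """Confusion matrix as a DataFrame, true classes as rows."""
    return pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes))
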