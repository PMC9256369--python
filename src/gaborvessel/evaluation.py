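"""Pixel-level evaluation of segmented vessel masks: confusion counts,
sensitivity / accuracy / specificity, the segmentation-regime taxonomy,
and per-image results tables with an average row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging_core import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricTriple",
    "confusion_counts",
    "metric_triple",
    "classify_regime",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / TN / FP / FN pixel counts over the evaluated region."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricTriple:
    """Sensitivity, accuracy, specificity; NaN marks an undefined value
    (zero denominator), which is excluded from averages."""

    sensitivity: float
    accuracy: float
    specificity: float


def confusion_counts(
    pred: BinaryMask, truth: BinaryMask, fov: BinaryMask | None = None
) -> ConfusionCounts:
    """Count agreement between predicted and ground-truth vessel masks,
    restricted to the field of view when one is given."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks must share one shape")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != pred.shape:
            raise ValueError("FOV mask must share the prediction's shape")
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metric_triple(counts: ConfusionCounts) -> MetricTriple:
    """Sen = TP/(TP+FN), Acc = (TP+TN)/total, Sp = TN/(FP+TN).

    Zero-denominator cases yield NaN rather than raising.
    """
    return MetricTriple(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
    )


def classify_regime(m: MetricTriple, high_cut: float = 0.9, low_cut: float = 0.5) -> str:
    """Qualitative segmentation regime.

    High specificity with low sensitivity = vessels missed
    (under-segmented); the reverse = background claimed as vessel
    (over-segmented); both high = accurate; anything else
    indeterminate.
    """
    sen, sp = m.sensitivity, m.specificity
    if math.isnan(sen) or math.isnan(sp):
        raise ValueError("regime classification needs defined Sen and Sp")
    if sp >= high_cut and sen >= high_cut:
        return "accurate"
    if sp >= high_cut and sen <= low_cut:
        return "under_segmented"
    if sp <= low_cut and sen >= high_cut:
        return "over_segmented"
    return "indeterminate"


def evaluate_set(
    pairs: Iterable[tuple[BinaryMask, BinaryMask, BinaryMask | None]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-image Sen/Acc/Sp table with a final unweighted-mean row.

    ``pairs`` yields (prediction, truth, fov-or-None) triples.  NaN
    (undefined) entries are excluded from the averages.  The frame has
    columns image / sensitivity / accuracy / specificity and is directly
    serializable as CSV.
    """
    rows = []
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_set needs at least one image")
    if labels is None:
        labels = [f"image_{i:02d}" for i in range(len(pairs))]
    for label, (pred, truth, fov) in zip(labels, pairs, strict=True):
        m = metric_triple(confusion_counts(pred, truth, fov))
        rows.append((label, m.sensitivity, m.accuracy, m.specificity))
    df = pd.DataFrame(rows, columns=["image", "sensitivity", "accuracy", "specificity"])
    means = df[["sensitivity", "accuracy", "specificity"]].mean(skipna=True)
    df.loc[len(df)] = ["Average value", *means]
    return df
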