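"""Pixel-level segmentation metrics: accuracy, specificity, sensitivity, IoU, Dice.

The ulcer is the positive class.  Undefined ratios (e.g. sensitivity on an
image with no true ulcer pixels) are reported as missing (None / NaN), never
as zero, so healthy-eye images do not silently drag down aggregate
sensitivity.  Batch evaluation reports aggregates under both conventions —
metrics of pooled counts, and the mean of per-image metrics — because the
two can differ materially and published tables rarely say which was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ShapeMismatchError
from .io import validate_mask


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five ratios; undefined ones are None."""

    accuracy: float
    specificity: float | None
    sensitivity: float | None
    iou: float | None
    dice: float | None
    counts: ConfusionCounts


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between a predicted and a reference mask."""
    validate_mask(pred)
    validate_mask(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(
            f"prediction {pred.shape} and truth {truth.shape} differ in shape"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, specificity, sensitivity, IoU (Jaccard) and Dice from counts."""
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = (tp + tn) / counts.total
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    denom = tp + fp + fn
    iou = tp / denom if denom > 0 else None
    dice = 2 * tp / (2 * tp + fp + fn) if denom > 0 else None
    return MetricsReport(
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        iou=iou,
        dice=dice,
        counts=counts,
    )


_METRIC_COLS = ["accuracy", "specificity", "sensitivity", "iou", "dice"]


def _row(report: MetricsReport) -> dict:
    d = {k: getattr(report, k) for k in _METRIC_COLS}
    d.update(
        tp=report.counts.tp,
        tn=report.counts.tn,
        fp=report.counts.fp,
        fn=report.counts.fn,
    )
    return d


def evaluate_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-image metric rows plus two labeled aggregate rows.

    Aggregates: ``pooled`` (metrics of summed counts) and ``per_image_mean``
    (mean of per-image metrics, skipping undefined values).  Shape mismatches
    raise with the offending id named.
    """
    if not pairs:
        raise ValueError("evaluate_batch needs at least one (pred, truth) pair")
    if ids is None:
        ids = [str(i) for i in range(len(pairs))]
    if len(ids) != len(pairs):
        raise ValueError("ids and pairs must have equal length")
    rows = []
    pooled = np.zeros(4, dtype=np.int64)  # tp, tn, fp, fn
    for img_id, (pred, truth) in zip(ids, pairs):
        try:
            counts = confusion(pred, truth)
        except ShapeMismatchError as exc:
            raise ShapeMismatchError(f"image {img_id!r}: {exc}") from exc
        pooled += (counts.tp, counts.tn, counts.fp, counts.fn)
        rows.append({"id": img_id, **_row(compute_metrics(counts))})
    frame = pd.DataFrame(rows)
    pooled_counts = ConfusionCounts(*(int(v) for v in pooled))
    pooled_row = {"id": "pooled", **_row(compute_metrics(pooled_counts))}
    mean_row = {"id": "per_image_mean"}
    for col in _METRIC_COLS:
        vals = frame[col].dropna()
        mean_row[col] = float(vals.mean()) if len(vals) else None
    for col in ("tp", "tn", "fp", "fn"):
        mean_row[col] = float(frame[col].mean())
    return pd.concat(
        [frame, pd.DataFrame([pooled_row, mean_row])], ignore_index=True
    )
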