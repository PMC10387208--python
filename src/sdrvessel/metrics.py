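"""Segmentation evaluation: pixel confusion counts and the four indicators
dice, accuracy, binary mIoU and recall, plus per-image / aggregate reporting.

Formulas (vessel = positive class):

    dice     = 2TP / (2TP + FP + FN)
    accuracy = (TP + TN) / (TP + TN + FP + FN)
    mIoU     = TP / (2(TP + FP + FN)) + TN / (2(TN + FP + FN))
             = mean of foreground IoU and background IoU
    recall   = TP / (TP + FN)

Degenerate denominators (e.g. an all-background ground truth makes recall
undefined) return 1.0 when the corresponding error counts are also zero and
0.0 otherwise, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "accuracy",
    "miou_binary",
    "recall",
    "all_metrics",
    "metrics_report",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion_counts(pred, truth, region=None) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over all pixels, or only where ``region`` == 1."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if region is not None:
        r = _check_binary(region, "region")
        if r.shape != p.shape:
            raise ValueError(f"region shape {r.shape} does not match maps {p.shape}")
        p, t = p[r], t[r]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _safe_ratio(num: float, den: float, errors: float, what: str) -> float:
    if den > 0:
        return num / den
    warnings.warn(f"{what} undefined (zero denominator); returning {1.0 if errors == 0 else 0.0}")
    return 1.0 if errors == 0 else 0.0


def dice(c: ConfusionCounts) -> float:
    return _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp + c.fn, "dice")


def accuracy(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp + c.tn, c.total, c.fp + c.fn, "accuracy")


def miou_binary(c: ConfusionCounts) -> float:
    fg = _safe_ratio(c.tp, 2 * (c.tp + c.fp + c.fn), c.fp + c.fn, "foreground IoU") if (c.tp + c.fp + c.fn) else 0.5
    bg = _safe_ratio(c.tn, 2 * (c.tn + c.fp + c.fn), c.fp + c.fn, "background IoU") if (c.tn + c.fp + c.fn) else 0.5
    return fg + bg


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, c.fp + c.fn, "recall")


def all_metrics(c: ConfusionCounts) -> dict:
    return {"dice": dice(c), "acc": accuracy(c), "miou": miou_binary(c), "recall": recall(c)}


def metrics_report(preds, truths, ids, threshold: float, regions=None,
                   aggregation: str = "macro") -> pd.DataFrame:
    """Per-image metric rows plus an aggregate row.

    ``macro`` aggregation (default) averages per-image metrics; ``micro``
    pools the confusion counts first.
    """
    if aggregation not in ("macro", "micro"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    rows = []
    counts = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        region = regions[i] if regions is not None else None
        c = confusion_counts(p, t, region)
        counts.append(c)
        rows.append({"image_id": ids[i], **all_metrics(c), "threshold": threshold})
    df = pd.DataFrame(rows)
    if aggregation == "macro":
        agg = {k: df[k].mean() for k in ("dice", "acc", "miou", "recall")}
    else:
        pooled = ConfusionCounts(0, 0, 0, 0)
        for c in counts:
            pooled = pooled + c
        agg = all_metrics(pooled)
    df.loc[len(df)] = {"image_id": f"aggregate_{aggregation}", **agg, "threshold": threshold}
    return df
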