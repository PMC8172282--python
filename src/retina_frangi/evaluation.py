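"""Pixelwise segmentation evaluation: Acc, Se, Sp over an evaluation region.

TP/FP count vessel and background pixels labeled vessel by the prediction;
FN/TN count vessel and background pixels labeled background.  Accuracy is
the fraction of correctly labeled pixels, sensitivity the vessel-pixel
recall TP/(TP+FN), specificity the background-pixel recall TN/(TN+FP).
Counts are restricted to the evaluation region (conventionally the FOV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    acc: float
    se: float
    sp: float


def confusion(pred: np.ndarray, truth: np.ndarray,
              region: np.ndarray | None = None) -> ConfusionCounts:
    """TP/FP/FN/TN tallies over region-restricted pixels."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if region is None:
        region = np.ones(pred.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != pred.shape:
        raise ValueError(
            f"shape mismatch: region {region.shape} vs pred {pred.shape}")
    p = pred[region]
    t = truth[region]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Acc = (TP+TN)/total, Se = TP/(TP+FN), Sp = TN/(TN+FP)."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive pixels in truth: Se denominator "
                         "(TP + FN) is zero")
    if c.tn + c.fp == 0:
        raise ValueError("no negative pixels in truth: Sp denominator "
                         "(TN + FP) is zero")
    return Metrics(
        acc=(c.tp + c.tn) / c.total,
        se=c.tp / (c.tp + c.fn),
        sp=c.tn / (c.tn + c.fp),
    )


def dice(pred: np.ndarray, truth: np.ndarray,
         region: np.ndarray | None = None) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) over the evaluation region."""
    c = confusion(pred, truth, region)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom
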