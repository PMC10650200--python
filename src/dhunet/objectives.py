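"""Training objectives and evaluation metrics for binary segmentation.

Two training strategies are supported: minimising pixelwise binary
cross-entropy, and maximising the soft Dice index by minimising
``1 - Dice``.  Evaluation reports precision, recall, F1 and Dice from
pixelwise confusion counts, either pooled over all pixels of a set
(micro / "global") or averaged per image (macro / "per-image-mean").

Conventions on degenerate cases, fixed once: 0/0 yields 0 for precision,
recall and F1; the Dice of two empty masks is 1 (via the smoothing term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

BCE_EPS = 1e-7
DICE_SMOOTH = 1e-6


def _flat_pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValidationError(
            f"mask pair length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def bce_loss(y, y_hat) -> float:
    """Mean binary cross-entropy; predictions are clipped to [eps, 1-eps]."""
    y, p = _flat_pair(y, y_hat)
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())


def dice_index(y, y_hat, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice overlap: (2 sum(y*yhat) + s) / (sum(y^2) + sum(yhat^2) + s)."""
    y, p = _flat_pair(y, y_hat)
    num = 2.0 * (y * p).sum() + smooth
    den = (y * y).sum() + (p * p).sum() + smooth
    return float(num / den)


def dice_loss(y, y_hat, smooth: float = DICE_SMOOTH) -> float:
    """Complement of the Dice index, used as the second training objective."""
    return 1.0 - dice_index(y, y_hat, smooth)


@dataclass(frozen=True)
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


def confusion_counts(y, y_hat_soft, threshold: float = 0.5) -> ConfusionCounts:
    """Binarise predictions at ``threshold`` (>= convention) and count
    pixelwise TP/FP/FN/TN."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    y, p = _flat_pair(y, y_hat_soft)
    pred = p >= threshold
    truth = y >= 0.5
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F1/Dice for one output head under one aggregation."""

    precision: float
    recall: float
    f1: float
    dice: float
    counts: ConfusionCounts | None = None
    head: int = 0
    aggregation: str = "global"
    strategy: str = ""


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def segmentation_metrics(counts: ConfusionCounts, pair=None, head: int = 0,
                         aggregation: str = "global",
                         strategy: str = "") -> MetricsReport:
    """Precision, recall and F1 from confusion counts; Dice from the
    binarised pair when given, else from the algebraically identical
    ``2TP / (2TP + FP + FN)`` form."""
    p = _safe_div(counts.tp, counts.tp + counts.fp)
    r = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2.0 * p * r, p + r)
    if pair is not None:
        y, y_hat = pair
        dice = dice_index(np.asarray(y), (np.asarray(y_hat) >= 0.5).astype(float))
    else:
        denom = 2.0 * counts.tp + counts.fp + counts.fn
        dice = (2.0 * counts.tp / denom) if denom > 0 else 1.0
    return MetricsReport(precision=p, recall=r, f1=f1, dice=dice,
                         counts=counts, head=head, aggregation=aggregation,
                         strategy=strategy)
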