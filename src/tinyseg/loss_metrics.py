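"""Class-imbalance weighted cross-entropy and recall-weighted metrics.

Foreground objects (3-10 px particles) occupy well under 1% of the
pixels, so an unweighted cross-entropy is dominated by the background
class.  The loss here weights each pixel by the inverse class frequency
of its ground-truth image: ``w_T = P / sum(Y)`` for foreground and
``w_F = P / (P - sum(Y))`` for background, where ``P`` is the pixel
count of one mask.  The per-image loss is the weighted cross-entropy
summed over pixels; a batch is averaged over its images.

For evaluation, plain recall/precision/F1/mIoU are complemented by
recall-weighted variants (``rw_f1 = f1 * recall``,
``rw_miou = miou * recall``): when the goal is to physically remove
every particle, a model that finds all of them at modest precision is
preferable to one with balanced but mediocre recall, and multiplying by
recall encodes exactly that preference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateMaskError", "LossWeights", "ConfusionCounts", "SegMetrics",
    "class_weights", "weighted_bce", "confusion_counts", "metric_suite",
    "binarize",
]


class DegenerateMaskError(ValueError):
    """Mask is all-foreground or all-background: class weights undefined."""


@dataclass(frozen=True)
class LossWeights:
    wT: float  # foreground (true-class) weight
    wF: float  # background (false-class) weight


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
class SegMetrics:
    recall: float
    precision: float
    f1: float
    miou: float
    rw_f1: float
    rw_miou: float


def class_weights(mask: np.ndarray, pixel_count: int | None = None
                  ) -> LossWeights:
    """Inverse-frequency class weights of one binary mask.

    Raises :class:`DegenerateMaskError` when the mask has no foreground
    or no background pixel (one of the weights would divide by zero).
    """
    y = np.asarray(mask)
    p = int(pixel_count) if pixel_count is not None else y.size
    s = float(y.sum())
    if s <= 0 or s >= p:
        raise DegenerateMaskError(
            f"mask with {s:.0f}/{p} foreground pixels has undefined "
            "class weights")
    return LossWeights(wT=p / s, wF=p / (p - s))


def _weight_mat(y: np.ndarray, safe: bool) -> np.ndarray:
    """Per-pixel weight map ``Y*wT + (1-Y)*wF`` for a batch of masks.

    With ``safe=True`` an all-background mask gets a unit background
    weight instead of raising (useful during training on crops that may
    contain no particle).
    """
    n = y.shape[0]
    p = y[0].size
    w = np.empty_like(y, dtype=np.float64)
    for i in range(n):
        s = float(y[i].sum())
        if 0 < s < p:
            lw = class_weights(y[i], p)
            w[i] = np.where(y[i] > 0, lw.wT, lw.wF)
        elif safe:
            w[i] = 1.0
        else:
            raise DegenerateMaskError(
                f"batch item {i} is degenerate ({s:.0f}/{p} foreground)")
    return w


def weighted_bce(y_true: np.ndarray, y_pred: np.ndarray,
                 weights: LossWeights | None = None, eps: float = 1e-7,
                 safe: bool = False) -> float:
    """Weighted binary cross-entropy of a batch of predictions.

    ``y_true`` and ``y_pred`` have identical shapes, either one image
    (H, W) or a batch (n, H, W).  Predictions are clamped to
    ``[eps, 1-eps]`` before the logarithm.  The per-image weighted
    cross-entropy is summed over pixels and the batch dimension is
    averaged.  ``weights`` overrides the per-image class weights.
    """
    y = np.asarray(y_true, dtype=np.float64)
    q = np.asarray(y_pred, dtype=np.float64)
    if y.shape != q.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {q.shape}")
    if y.ndim == 2:
        y, q = y[None], q[None]
    if ((y != 0) & (y != 1)).any():
        raise ValueError("ground truth must be binary")
    q = np.clip(q, eps, 1.0 - eps)
    if weights is not None:
        w = np.where(y > 0, weights.wT, weights.wF)
    else:
        w = _weight_mat(y, safe=safe)
    ce = -(y * np.log(q) + (1.0 - y) * np.log(1.0 - q))
    return float((ce * w).reshape(y.shape[0], -1).sum(axis=1).mean())


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict thresholding: a pixel is foreground iff prob > threshold."""
    return np.asarray(prob) > threshold


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray
                     ) -> ConfusionCounts:
    """Pixel-level confusion counts of two binary masks (any shape)."""
    y = np.asarray(y_true).astype(bool)
    q = np.asarray(y_pred).astype(bool)
    if y.shape != q.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {q.shape}")
    tp = int(np.count_nonzero(y & q))
    fp = int(np.count_nonzero(~y & q))
    fn = int(np.count_nonzero(y & ~q))
    tn = y.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def metric_suite(c: ConfusionCounts) -> SegMetrics:
    """Recall, precision, F1, mIoU and their recall-weighted variants.

    Requires at least one true foreground pixel (recall is undefined
    otherwise).  Zero-denominator conventions: precision is 0 when
    nothing is predicted positive; F1 is 0 when precision and recall
    are both 0 (these reproduce the all-zero rows a collapsed model
    produces).
    """
    if c.tp + c.fn == 0:
        raise DegenerateMaskError(
            "no foreground pixels in ground truth: recall undefined")
    recall = c.tp / (c.tp + c.fn)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    miou = c.tp / (c.tp + c.fp + c.fn)
    return SegMetrics(recall=recall, precision=precision, f1=f1, miou=miou,
                      rw_f1=f1 * recall, rw_miou=miou * recall)
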