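"""Lung masks and bounding-box cropping.

External masks, when a manifest provides them, take precedence; the
fallback here is a deliberately simple non-learned segmenter (Otsu
threshold, morphological opening, two largest components) that is adequate
for phantom-grade imagery and for smoke-testing the pipeline on real films.
"""

from __future__ import annotations

import numpy as np
from skimage import filters, measure, morphology

from .preprocess import equalize_histogram


class EmptyMaskError(ValueError):
    pass


def segment_lungs_fallback(image: np.ndarray) -> np.ndarray:
    """Threshold-based two-component lung mask.

    Otsu on the equalized image, opening with a disk of radius side/32,
    then keep the two largest connected components (or one, if only one
    survives).  Raises :class:`EmptyMaskError` when nothing is foreground.
    """
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        raise EmptyMaskError("image has no contrast; cannot segment")
    eq = equalize_histogram(image)
    thresh = filters.threshold_otsu(eq)
    fg = eq > thresh
    radius = max(1, image.shape[0] // 32)
    fg = morphology.opening(fg, morphology.disk(radius))
    labels = measure.label(fg)
    if labels.max() == 0:
        raise EmptyMaskError("no foreground component above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argsort(sizes)[::-1][:2] + 1
    return np.isin(labels, keep).astype(np.uint8)


def crop_to_mask_bbox(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tight axis-aligned crop to the mask foreground (half-open bounds)."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("cannot crop to an empty mask")
    return image[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def iou_dice(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Intersection-over-union and Dice overlap; two empty masks give (1, 1)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2.0 * inter / (a.sum() + b.sum())
    return float(iou), float(dice)
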