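"""Image conditioning and dataset partitioning.

Operations mirror the standard triage preprocessing chain: 256-bin
histogram equalization for contrast, bilinear down-sampling to a square
working resolution, a seeded 70/30 train/test split, and light geometric
augmentation (small rotations plus integer pixel shifts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class AugmentSpec:
    """Rotation uniform in [0, rotation_range_deg]; shifts uniform in
    +/- fraction of the side length, applied as whole-pixel translations."""

    rotation_range_deg: float = 10.0
    width_shift_frac: float = 0.2
    height_shift_frac: float = 0.2


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    return image


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin cumulative-histogram equalization onto [0, 1].

    The mapping is a monotone function of pixel rank, so relative ordering
    is preserved; a constant image maps to a constant.  256 bins are used
    regardless of the source bit depth so 8- and 12-bit films share one
    deterministic dialect.
    """
    image = _check_image(image)
    if image.max() == image.min():
        return image.copy()
    return exposure.equalize_hist(image, nbins=256)


def resize(image: np.ndarray, target_side: int) -> np.ndarray:
    """Bilinear resize to ``target_side`` square, clipped to [0, 1]."""
    image = _check_image(image)
    if target_side < 8:
        raise ValueError("target_side must be >= 8")
    if image.shape == (target_side, target_side):
        return image.copy()
    out = transform.resize(image, (target_side, target_side), order=1,
                           anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def split_dataset(case_ids: list[str], spec: SplitSpec = SplitSpec()) -> tuple[list[str], list[str]]:
    """Uniform shuffle, then round-half-up on train_fraction * N.

    Round-half-up reproduces the canonical 2480 -> 1736/744 partition at
    the default 70% fraction.
    """
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(case_ids))
    n_train = int(np.floor(spec.train_fraction * len(case_ids) + 0.5))
    train = [case_ids[i] for i in order[:n_train]]
    test = [case_ids[i] for i in order[n_train:]]
    return train, test


def augment(image: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Random rotation followed by a whole-pixel shift; zeros fill the frame."""
    image = _check_image(image)
    if image.shape[0] != image.shape[1]:
        raise ValueError("augment expects a square image")
    side = image.shape[0]
    angle = rng.uniform(0.0, spec.rotation_range_deg)
    dy = int(round(rng.uniform(-spec.height_shift_frac, spec.height_shift_frac) * side))
    dx = int(round(rng.uniform(-spec.width_shift_frac, spec.width_shift_frac) * side))
    out = image
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    if dy or dx:
        out = ndimage.shift(out, (dy, dx), order=0, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def shift_image(image: np.ndarray, dy_frac: float, dx_frac: float) -> np.ndarray:
    """Deterministic shift by round(frac * side) pixels (zero fill)."""
    image = _check_image(image)
    side = image.shape[0]
    dy, dx = int(round(dy_frac * side)), int(round(dx_frac * side))
    return ndimage.shift(image, (dy, dx), order=0, mode="constant", cval=0.0)
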