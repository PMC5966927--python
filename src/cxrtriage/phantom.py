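"""Seeded radiograph-like phantom generator.

The phantoms emulate a frontal chest film at desk scale: two bright
elliptical lung fields on a darker thorax background, low-amplitude
horizontal rib banding, additive Gaussian pixel noise, and — in abnormal
cases — one or more blob-shaped lesions placed inside a lung field.  The
ground-truth mask is the union of the two lung ellipses.  Everything is a
pure function of (config, seed) so the rest of the pipeline is testable
without any external imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: background / lung-field base intensities ([0,1] scale)
_BACKGROUND = 0.15
_LUNG = 0.55
_RIB_AMPLITUDE = 0.05  # low-amplitude sinusoidal banding
_RIB_PERIOD_FRAC = 0.12  # rib spacing as a fraction of image side


@dataclass
class PhantomConfig:
    """Generator settings.

    ``image_size`` defaults to 64 so an autoencoder trains in seconds;
    512 mirrors full-resolution film.  ``imbalance_ratio`` is the
    normal:abnormal ratio used when ``n_normal`` is not given explicitly
    (3.15:1 matches the prevalence the pipeline is designed around).
    """

    image_size: int = 64
    n_normal: int | None = None
    n_abnormal: int = 20
    imbalance_ratio: float = 3.15
    lesion_radius_range: tuple[float, float] = (4.0, 8.0)
    lesion_contrast: float = 0.4
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0.0 < self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must be in (0, 1]")
        if self.n_abnormal < 0 or (self.n_normal is not None and self.n_normal < 0):
            raise ValueError("case counts must be >= 0")
        if self.n_normal is None:
            self.n_normal = int(round(self.imbalance_ratio * self.n_abnormal))


@dataclass
class LabeledImage:
    image: np.ndarray  # float in [0, 1]
    mask: np.ndarray  # uint8 in {0, 1}
    label: int  # 0 normal, 1 abnormal
    case_id: str
    lesion_centers: list[tuple[int, int]] = field(default_factory=list)
    lesion_radii: list[float] = field(default_factory=list)


def _lung_ellipses(size: int, rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    """Two lung fields as (cy, cx, semi_y, semi_x), jittered per case."""
    jit = lambda s: rng.uniform(-s, s)
    params = []
    for cx_frac in (0.32, 0.68):
        cy = size * (0.50 + jit(0.02))
        cx = size * (cx_frac + jit(0.02))
        sy = size * (0.32 + jit(0.02))
        sx = size * (0.14 + jit(0.015))
        params.append((cy, cx, sy, sx))
    return params


def generate_phantom(config: PhantomConfig, abnormal: bool,
                     rng: np.random.Generator, case_id: str = "case") -> LabeledImage:
    """Render a single phantom with its ground-truth lung mask.

    Lesions are additive 2-D Gaussian blobs (sigma = radius / 2) of the
    configured peak contrast, centred strictly inside a lung ellipse;
    intensities are clipped to [0, 1] afterwards.
    """
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size), _BACKGROUND)
    mask = np.zeros((size, size), dtype=np.uint8)

    ellipses = _lung_ellipses(size, rng)
    for cy, cx, sy, sx in ellipses:
        inside = ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1.0
        img[inside] = _LUNG
        mask |= inside.astype(np.uint8)

    # rib banding: horizontal sinusoid, visible mostly over the lungs
    phase = rng.uniform(0.0, 2 * np.pi)
    ribs = _RIB_AMPLITUDE * np.sin(2 * np.pi * yy / (size * _RIB_PERIOD_FRAC) + phase)
    img += ribs * (0.3 + 0.7 * mask)

    centers: list[tuple[int, int]] = []
    radii: list[float] = []
    if abnormal:
        n_lesions = int(rng.integers(1, 3))
        for _ in range(n_lesions):
            cy, cx, sy, sx = ellipses[int(rng.integers(0, 2))]
            # sample inside the ellipse at <= 60% of each semi-axis
            while True:
                u, v = rng.uniform(-0.6, 0.6, size=2)
                if u * u + v * v <= 0.36:
                    break
            ly, lx = cy + u * sy, cx + v * sx
            radius = rng.uniform(*config.lesion_radius_range)
            sigma = radius / 2.0
            blob = config.lesion_contrast * np.exp(
                -((yy - ly) ** 2 + (xx - lx) ** 2) / (2.0 * sigma * sigma))
            img += blob
            centers.append((int(round(ly)), int(round(lx))))
            radii.append(radius)

    img += config.noise_sd * rng.standard_normal((size, size))
    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(image=img, mask=mask, label=int(abnormal),
                        case_id=case_id, lesion_centers=centers, lesion_radii=radii)


def generate_dataset(config: PhantomConfig) -> list[LabeledImage]:
    """All requested cases, normals first, ids ``normal_0000`` / ``abnormal_0000``."""
    if config.n_normal + config.n_abnormal == 0:
        raise ValueError("requested an empty dataset")
    rng = np.random.default_rng(config.seed)
    cases = [generate_phantom(config, False, rng, f"normal_{i:04d}")
             for i in range(config.n_normal)]
    cases += [generate_phantom(config, True, rng, f"abnormal_{i:04d}")
              for i in range(config.n_abnormal)]
    return cases


def generate_feature_table(n_per_class: tuple[int, int], dim: int, class_shift: float,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian feature fixture: class 0 about the origin, class 1 shifted.

    The shift is applied along a fixed unit direction (the first axis), so
    separability is controlled by ``class_shift`` against unit noise.
    Returns ``(features, labels)`` with class-0 rows first.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    n0, n1 = n_per_class
    x0 = rng.standard_normal((n0, dim))
    x1 = rng.standard_normal((n1, dim))
    x1[:, 0] += class_shift
    features = np.vstack([x0, x1])
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return features, labels
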