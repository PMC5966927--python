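"""Fixed-length image features, normalization, and class rebalancing.

The extractor contract is pluggable: any callable mapping an image to a
fixed-length vector qualifies (a pretrained backbone adapter that pools or
projects to 512 dimensions fits the same slot).  The built-in extractor is
fully deterministic and needs no external weights: a 16x16 mean-pooled
intensity grid (256 values), a 128-bin intensity histogram, down-sampled
row/column mean profiles (32 + 32), and an 8x8 mean-pooled gradient
magnitude grid (64) — 512 dimensions in total.

Rebalancers (SMOTE, Tomek-link removal, edited nearest neighbours) follow
the classical definitions with Euclidean distances and lowest-index tie
breaking so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np

FEATURE_DIM = 512
_EPS = 1e-8


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _mean_pool(image: np.ndarray, grid: int) -> np.ndarray:
    h, w = image.shape
    # crop to a multiple of the grid so the reshape is exact
    h2, w2 = (h // grid) * grid, (w // grid) * grid
    x = image[:h2, :w2]
    return x.reshape(grid, h2 // grid, grid, w2 // grid).mean(axis=(1, 3))


def _profile(vec: np.ndarray, length: int) -> np.ndarray:
    idx = np.linspace(0, vec.size - 1, length)
    return np.interp(idx, np.arange(vec.size), vec)


def builtin_extractor(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    pooled = _mean_pool(image, 16).ravel()                       # 256
    hist, _ = np.histogram(image, bins=128, range=(0.0, 1.0))    # 128
    hist = hist / image.size
    rows = _profile(image.mean(axis=1), 32)                      # 32
    cols = _profile(image.mean(axis=0), 32)                      # 32
    gy, gx = np.gradient(image)
    grad = _mean_pool(np.hypot(gy, gx), 8).ravel()               # 64
    vec = np.concatenate([pooled, hist, rows, cols, grad])
    assert vec.size == FEATURE_DIM
    return vec


EXTRACTORS = {"builtin": builtin_extractor}


def extract_features(image: np.ndarray, extractor: str = "builtin") -> np.ndarray:
    """Length-512 feature vector for one preprocessed image."""
    try:
        fn = EXTRACTORS[extractor]
    except KeyError:
        raise ValueError(f"unknown extractor {extractor!r}; have {sorted(EXTRACTORS)}")
    vec = fn(image)
    if not np.all(np.isfinite(vec)):
        raise ValueError("extractor produced non-finite values")
    return vec


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class NormalizationStats:
    """Per-dimension mean/std estimated on the training features only."""

    def __init__(self, train: np.ndarray):
        train = np.asarray(train, dtype=float)
        self.mean = train.mean(axis=0)
        self.std = np.maximum(train.std(axis=0), _EPS)

    def apply(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.mean.size:
            raise ValueError("feature dimensionality mismatch")
        return (features - self.mean) / self.std


def normalize_features(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    """z-score ``apply_to`` using statistics of ``train`` (never of itself)."""
    return NormalizationStats(train).apply(apply_to)


# ---------------------------------------------------------------------------
# rebalancing
# ---------------------------------------------------------------------------

def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def smote(features: np.ndarray, labels: np.ndarray, k: int = 5,
          target_count: int | None = None,
          rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling.

    New minority points are ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the k nearest minority neighbours of ``x`` (Euclidean,
    lowest index on ties).  The minority count is raised to
    ``target_count`` (default: the majority count).
    """
    rng = rng or np.random.default_rng(0)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    n_min = counts[minority]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(k, n_min - 1)
    if target_count is None:
        target_count = int(counts[majority])
    n_new = max(0, target_count - n_min)
    if n_new == 0:
        return features.copy(), labels.copy()

    minority_idx = np.flatnonzero(labels == minority)
    x_min = features[minority_idx]
    d2 = _pairwise_sq(x_min, x_min)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(n_new)
    x_base = x_min[base]
    x_nn = x_min[nn[base, pick]]
    synthetic = x_base + u[:, None] * (x_nn - x_base)

    out_x = np.vstack([features, synthetic])
    out_y = np.concatenate([labels, np.full(n_new, minority, dtype=int)])
    return out_x, out_y


def tomek_remove(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop the majority member of every Tomek link.

    A Tomek link is a pair of opposite-class points that are mutual
    nearest neighbours; removing its majority-class member cleans the class
    boundary after over-sampling.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        return features.copy(), labels.copy()
    counts = np.bincount(labels, minlength=2)
    majority = int(np.argmax(counts))
    d2 = _pairwise_sq(features, features)
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)  # lowest index on ties
    drop = np.zeros(len(labels), dtype=bool)
    for i in range(len(labels)):
        j = nn[i]
        if nn[j] == i and labels[i] != labels[j]:
            drop[i if labels[i] == majority else j] = True
    keep = ~drop
    out_y = labels[keep]
    if len(set(out_y.tolist())) < 2:
        warnings.warn("Tomek-link removal left a single class", stacklevel=2)
    return features[keep], out_y


def enn_clean(features: np.ndarray, labels: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Edited nearest neighbours: drop samples misclassified by their k-NN vote.

    The vote excludes the sample itself; exact ties keep the sample.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n <= k:
        raise ValueError(f"need more than k={k} samples")
    d2 = _pairwise_sq(features, features)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = labels[nn].mean(axis=1)
    agree = np.where(labels == 1, votes >= 0.5, votes <= 0.5)
    keep = agree
    out_y = labels[keep]
    if len(set(out_y.tolist())) < 2 and len(set(labels.tolist())) == 2:
        warnings.warn("ENN cleaning left a single class", stacklevel=2)
    return features[keep], out_y


def rebalance(features: np.ndarray, labels: np.ndarray, method: str,
              rng: np.random.Generator | None = None,
              k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Named rebalancing condition: none / smote / smote_tk / smote_enn."""
    if method == "none":
        return np.asarray(features, float).copy(), np.asarray(labels, int).copy()
    x, y = smote(features, labels, k=k, rng=rng)
    if method == "smote":
        return x, y
    if method == "smote_tk":
        return tomek_remove(x, y)
    if method == "smote_enn":
        return enn_clean(x, y)
    raise ValueError(f"unknown rebalance method {method!r}")
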