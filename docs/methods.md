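# Methods

This note records the model implemented by `cxrtriage`, the assumptions and
default parameters, the numerical choices, and the known limitations.

## Problem

Screening chest radiographs are heavily imbalanced (normal : abnormal around
3.15 : 1) and reading every film is expensive. The package triages each film
into **normal**, **abnormal**, or **uncertain** so that definite verdicts can
be deprioritized or fast-tracked and reading effort concentrates on the
uncertain band. The design goal is *precision of the definite levels*, not
coverage: an uncertain verdict is always acceptable, a wrong definite verdict
is not.

## Model

Two independent abnormality scores are computed per film and then combined.

### Unsupervised branch: CSDAE reconstruction error

A convolutional sparse denoising autoencoder is trained on **normal films
only**. Encoder: three 3×3 conv layers (16, 8, 8 filters, ReLU) each followed
by 2×2 max-pooling; decoder: three 3×3 conv layers (8, 8, 16 filters, ReLU)
each followed by 2×2 nearest-neighbour upsampling, then a 3×3 sigmoid conv
back to one channel. Per-layer parameter counts are 160, 1160, 584, 584, 584,
1168, 145 (total 4385), independent of spatial size. Training corrupts the
input with additive Gaussian noise (factor 0.01, clipped to [0, 1]) and
regresses onto the clean target under the cost

    J = ½·mean((x − y)²) + (λ_w/2)·Σ‖W‖² + λ_s·mean_batch(Σ|a_bottleneck|)

with sparsity weight λ_s = 1e−5, weight decay λ_w = 0 by default, Adam at
learning rate 1e−4, batch size 62. A film's anomaly score C2 is its mean
squared reconstruction error: lesions are structures the normal-only model
cannot reproduce, so abnormal films reconstruct worse.

### Supervised branch: classifier head on 512-dim features

Images are mapped to fixed 512-dimensional feature vectors by a pluggable
extractor. The deterministic built-in extractor concatenates 16×16 mean-pool
intensities (256), a 128-bin histogram, row and column profiles (32 + 32), and
8×8-pooled gradient magnitudes (64). Features are z-scored with training-set
statistics. The head is three (batchnorm → dropout → dense-512-ReLU) blocks
ending in a single sigmoid unit (parameter counts 2048, 262656, 2048, 262656,
2048, 513; total 531969), trained with Adam at 3e−5, batch 62, dropout 0.25,
L1 weight penalty 1e−5, and either cross-entropy or the focal loss
−α(1−p_t)^γ·ln p_t with α = γ = 0.1. Its abnormality probability is score C1.

### Imbalance handling

Training features may be rebalanced by SMOTE (synthetic minority points on
segments between minority nearest neighbours), optionally followed by
Tomek-link removal or edited-nearest-neighbour cleaning (k = 3). All neighbour
searches are Euclidean with lowest-index tie-breaks for determinism.
Rebalancing touches training data only.

### Score combination and the three-level vote

* **Linear combination.** f_b(C) = C1 + Σ b_k·C_k, with the coefficients
  chosen to maximize the empirical AUC — the Mann–Whitney probability that a
  random abnormal outscores a random normal, ties credited ½ — over a grid
  (0 plus ±41 log-spaced magnitudes in [1e−3, 1e3], since C1 ≈ 1 and
  C2 ≈ 1e−3 live on different scales). Ties prefer the smallest coefficient
  norm, then enumeration order, so duplicated predictors get coefficient 0.
* **Threshold rule.** An error threshold T ∈ (0, T_mean) — T_mean the mean
  training reconstruction error — and a probability threshold P ∈ (0.5, 1)
  are grid-searched (default 25×25) to maximize the empirical AUC of the
  ordinal flag count 1[err > T] + 1[prob > P]; ties prefer smaller P, then
  smaller T.
* **Vote.** A panel — four classical baselines (KNN k = 5, logistic
  regression, calibrated RBF SVM, random forest with 100 trees), the head,
  and the threshold rule's "any flag" vote — decides by unanimity: all
  negative → normal, all positive → abnormal, any split → uncertain.
  Unanimity was chosen as the strictest reading of a multi-classifier vote;
  panel membership is configurable.

## Pipeline and reproducibility

`run_pipeline` chains: histogram equalization (256 bins) → lung masking
(manifest-provided masks take precedence; otherwise an Otsu + morphological
opening fallback keeping the two largest components) → crop to mask bounding
box → bilinear resize to `side` (default 64) → 70/30 split (round-half-up) →
optional augmentation (rotation up to 10°, integer shifts up to 0.2·side) →
features, rebalancing, head + baselines → CSDAE on normal training films →
combination and threshold fitting on training scores → panel vote on the test
set. One global seed derives each stage's seed as `crc32(stage_name) XOR seed
mod 2³¹`; identical configurations reproduce every artifact byte-for-byte.

## Phantom data

Phantoms are 64×64 (configurable) images with two bright elliptical lung
fields (intensity 0.55 on a 0.15 background), sinusoidal ribs (amplitude
0.05), i.i.d. Gaussian pixel noise (σ = 0.02), and — for abnormal cases — one
or two additive Gaussian-blob lesions (σ = radius/2, radius 4–8 px) centred
inside the lung mask. They exercise every contract (masks, labels, contrast,
imbalance) but are far easier than clinical films: no anatomy variation, no
projection artifacts, no device differences. Quantitative results on phantoms
(anomaly AUC ≈ 0.99 at contrast 0.5, end-to-end definite precision 1.0) are
smoke-level evidence of correct mechanics, not clinical performance claims.

## Problem sizes and defaults

Defaults are chosen so the full test suite runs in minutes on one CPU: 64×64
images, 83-case datasets, 30 CSDAE epochs, 60 head epochs. 512×512 images and
thousands of cases are supported by the same code paths (conv parameter counts
are side-invariant; memory scales with batch·side²). With very small training
sets one epoch is a single optimizer step, so epoch counts should be read as
step budgets.

## Numerical choices

* Forward/backward passes run in float32; loss reporting, AUC, and metric
  arithmetic in float64.
* The empirical AUC is computed from midranks in O(n log n) and is exactly
  equal to the brute-force pairwise count with half-credit ties.
* The strict Mann–Whitney indicator is softened with the standard ½ tie
  credit so a constant score gives AUC 0.5 rather than 0.
* Glorot-uniform initialization, seeded; inverted dropout; batchnorm keeps
  running statistics (momentum 0.9) for deterministic inference.

## Limitations

* **Definite-normal verdicts are rare under the default panel.** Whenever the
  head separates the *training* set perfectly, every (T, P) pair with T below
  the smallest training reconstruction error ties at training AUC 1.0, and
  the smaller-P-then-smaller-T tie-break selects a tiny T. The threshold
  rule's "any flag" vote then fires on every case, so a unanimous-normal
  verdict becomes impossible and definite verdicts are abnormal-only. This
  follows from the stated tie-break and panel semantics, and it is
  conservative (it only ever moves cases into the uncertain band, never into
  a wrong definite level); a max-margin tie-break or excluding the rule from
  the panel would trade this safety for coverage.
* **KNN under imbalance.** With 3.15 : 1 training imbalance, KNN (k = 5)
  votes majority-class almost everywhere and blocks unanimous-abnormal
  verdicts; runs on imbalanced manifests should use `balance="smote"` (or a
  SMOTE variant), which is also the methodologically intended configuration.
* The built-in feature extractor is a deterministic stand-in for a pretrained
  backbone; plug in a real backbone adapter (projected/pooled to 512) for
  clinical images.
* The lung-field fallback segmentation is intensity-based and tuned to
  phantom-like contrast; real films should supply masks via the manifest.
* Empirical-AUC maximization is a grid search; coefficients and thresholds
  are only optimal at grid resolution.
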