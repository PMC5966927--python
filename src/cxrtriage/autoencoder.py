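"""Convolutional sparse denoising autoencoder (CSDAE) and its plain-AE baseline.

The network learns to reconstruct a clean radiograph from a Gaussian-noise
corrupted copy, under an L1 sparsity penalty on the bottleneck activations.
Trained on normal films only, its per-image reconstruction MSE serves as an
anomaly score: structures absent from the normal training distribution
(lesions) reconstruct poorly and inflate the error.

Cost function (per batch)::

    L = 1/2 * mean((x - y)^2)  +  lambda_w/2 * sum(W^2)  +  lambda_s * mean_i(sum |a_i|)

where ``y`` is the reconstruction, ``a_i`` the bottleneck activation map of
case ``i``, ``lambda_s`` the sparsity weight (default 1e-5) and
``lambda_w`` an optional weight decay (default 0).  Setting
``noise_factor = 0`` and ``lambda_s = 0`` recovers the plain AE baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import LayerSpec, csdae_architecture
from .nn import Adam, Network, build_network


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 62
    epochs: int = 30
    sparsity_weight: float = 1e-5
    weight_decay: float = 0.0
    noise_factor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.weight_decay < 0 or self.noise_factor < 0 or self.sparsity_weight < 0:
            raise ValueError("regularization weights and noise_factor must be >= 0")


@dataclass
class NetworkState:
    """Trained network plus its provenance."""

    network: Network
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def side(self) -> int:
        return self.network.arch[0].shape[0]


def corrupt(image: np.ndarray, noise_factor: float, rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian corruption, clipped back to [0, 1]."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be >= 0")
    image = np.asarray(image, dtype=float)
    if noise_factor == 0:
        return image.copy()
    return np.clip(image + noise_factor * rng.standard_normal(image.shape), 0.0, 1.0)


def _to_batch(images: np.ndarray, dtype=np.float32) -> np.ndarray:
    x = np.asarray(images, dtype=dtype)
    if x.ndim == 2:
        x = x[None]
    return x[..., None] if x.ndim == 3 else x


def _bottleneck(network: Network, x4d: np.ndarray) -> np.ndarray:
    record = {network.tagged["bottleneck"]: None}
    network.forward(x4d, train=False, record=record)
    return record[network.tagged["bottleneck"]]


def reconstruction_loss(batch_in: np.ndarray, batch_out: np.ndarray,
                        state: NetworkState, config: TrainConfig) -> float:
    """Evaluate the cost function on an (input, reconstruction) pair.

    The bottleneck activations entering the sparsity term are obtained by
    encoding ``batch_in`` with ``state``'s network.
    """
    x = _to_batch(batch_in, dtype=float)
    y = _to_batch(batch_out, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    err = 0.5 * float(np.mean((x - y) ** 2))
    reg = 0.0
    if config.weight_decay > 0:
        reg += 0.5 * config.weight_decay * sum(float((w.astype(np.float64) ** 2).sum())
                                               for w in state.network.weight_matrices())
    if config.sparsity_weight > 0:
        a = _bottleneck(state.network, _to_batch(batch_in)).astype(np.float64)
        reg += config.sparsity_weight * float(np.abs(a).sum()) / a.shape[0]
    return err + reg


def train_autoencoder(images: np.ndarray, config: TrainConfig,
                      arch: list[LayerSpec] | None = None) -> NetworkState:
    """Corrupted-input / clean-target training with Adam.

    ``images`` is (N, side, side) in [0, 1].  The per-epoch mean batch loss
    is recorded in the returned state's ``loss_history``.
    """
    x = _to_batch(images)
    n, side = x.shape[0], x.shape[1]
    if arch is None:
        arch = csdae_architecture(side)
    rng = np.random.default_rng(config.seed)
    net = build_network(arch, rng)
    opt = Adam(net.params, net.grads, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    state = NetworkState(network=net, config=config)
    bn_idx = net.tagged["bottleneck"]
    batch = min(config.batch_size, n)
    npix = side * side

    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            clean = x[idx]
            noisy = clean
            if config.noise_factor > 0:
                noisy = np.clip(
                    clean + config.noise_factor
                    * rng.standard_normal(clean.shape).astype(np.float32), 0.0, 1.0)
            record = {bn_idx: None}
            out = net.forward(noisy, train=True, record=record)
            diff = out - clean
            m = idx.size
            loss = 0.5 * float(np.mean(diff ** 2))
            dout = diff / (m * npix)
            inject = None
            if config.sparsity_weight > 0:
                a = record[bn_idx]
                loss += config.sparsity_weight * float(np.abs(a).sum()) / m
                inject = {bn_idx: (config.sparsity_weight / m)
                          * np.sign(a).astype(np.float32)}
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; lower the learning rate")
            net.backward(dout, inject=inject)
            opt.step()
            losses.append(loss)
        state.loss_history.append(float(np.mean(losses)))
    return state


def reconstruction_error(state: NetworkState, image: np.ndarray) -> float:
    """Per-image mean squared reconstruction error on the *clean* input."""
    x = _to_batch(image)
    if x.shape[1] != state.side or x.shape[2] != state.side:
        raise ValueError(f"image side {x.shape[1:3]} does not match trained side {state.side}")
    out = state.network.forward(x, train=False)
    return float(np.mean((x - out) ** 2))


def reconstruction_errors(state: NetworkState, images: np.ndarray,
                          batch_size: int = 62) -> np.ndarray:
    """Vectorized per-image MSEs for a stack of images."""
    x = _to_batch(images)
    errs = []
    for start in range(0, x.shape[0], batch_size):
        chunk = x[start:start + batch_size]
        out = state.network.forward(chunk, train=False)
        errs.append(((chunk - out) ** 2).mean(axis=(1, 2, 3)))
    return np.concatenate(errs).astype(float)


def compare_ae_csdae(train_images: np.ndarray, test_images: np.ndarray,
                     noise_factors: tuple[float, ...] = (0.01, 0.05),
                     epochs: int = 30, seed: int = 0) -> dict:
    """Train the plain AE and the CSDAE at each noise factor; report MSEs.

    For each (model, factor): mean +/- std of per-image MSE on the training
    set, the clean test set, and a noise-corrupted copy of the test set.
    The AE baseline is the same architecture trained with no input
    corruption and no sparsity penalty.
    """
    rng = np.random.default_rng(seed)
    report: dict = {}
    for factor in noise_factors:
        for model_name, cfg in (
            ("AE", TrainConfig(noise_factor=0.0, sparsity_weight=0.0,
                               epochs=epochs, seed=seed)),
            ("CSDAE", TrainConfig(noise_factor=factor, epochs=epochs, seed=seed)),
        ):
            state = train_autoencoder(train_images, cfg)
            noised_test = corrupt(np.asarray(test_images, float), factor, rng)
            entry = {}
            for split_name, imgs in (("train", train_images), ("test", test_images),
                                     ("test_noised", noised_test)):
                errs = reconstruction_errors(state, np.asarray(imgs))
                entry[split_name] = {"mean": float(errs.mean()), "std": float(errs.std())}
            report[(model_name, factor)] = entry
    return report
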