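"""Supervised branch: feed-forward head on 512-dim features, plus baselines.

The head (batchnorm / dropout / dense blocks, sigmoid output) is trained
with either plain cross-entropy or the focal loss — cross-entropy
down-weighted by ``(1 - p_t)^gamma`` and scaled by ``alpha`` — under an L1
weight penalty.  Its output probability is the predictor C1 consumed by the
score-combination stage.  Four classical baselines (k-nearest-neighbours,
logistic regression, RBF support-vector machine, random forest) share one
probability interface for the comparison sweeps and for the triage vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .architecture import head_architecture
from .nn import Adam, Network, build_network

_P_CLIP = 1e-7


@dataclass
class HeadConfig:
    learning_rate: float = 3e-5
    batch_size: int = 62
    dropout_rate: float = 0.25
    l1_weight: float = 1e-5
    loss: str = "focal"
    focal_alpha: float = 0.1
    focal_gamma: float = 0.1
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError("loss must be 'cross_entropy' or 'focal'")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.dropout_rate not in (0.25, 0.5):
            raise ValueError("dropout_rate must be 0.25 or 0.5")


def _clip(p: np.ndarray | float) -> np.ndarray:
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


def cross_entropy(p, y) -> np.ndarray | float:
    """Binary cross-entropy, elementwise; probabilities clipped for stability."""
    p = _clip(np.asarray(p, dtype=float))
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def focal_loss(p, y, alpha: float, gamma: float) -> np.ndarray | float:
    """Focal loss: -alpha * (1 - p_t)^gamma * ln(p_t), p_t the true-class prob.

    Reduces to ``alpha *`` cross-entropy at gamma = 0; gamma > 0 discounts
    well-classified cases, concentrating the gradient on hard examples.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = _clip(np.asarray(p, dtype=float))
    y = np.asarray(y, dtype=float)
    pt = np.where(y == 1, p, 1.0 - p)
    return -alpha * (1.0 - pt) ** gamma * np.log(pt)


def _loss_grad_wrt_p(p: np.ndarray, y: np.ndarray, config: HeadConfig) -> np.ndarray:
    """d(loss)/dp for the configured loss (p already clipped)."""
    if config.loss == "cross_entropy":
        return np.where(y == 1, -1.0 / p, 1.0 / (1.0 - p))
    a, g = config.focal_alpha, config.focal_gamma
    pt = np.where(y == 1, p, 1.0 - p)
    # d/dpt [-a (1-pt)^g ln pt] = a*g*(1-pt)^(g-1)*ln(pt) - a*(1-pt)^g / pt
    dpt = a * g * (1.0 - pt) ** (g - 1.0) * np.log(pt) - a * (1.0 - pt) ** g / pt
    return np.where(y == 1, dpt, -dpt)


class TrainedHead:
    """Fitted head exposing the shared probability interface."""

    def __init__(self, network: Network, config: HeadConfig):
        self.network = network
        self.config = config
        self.name = "cnn_head"

    def predict_proba_abnormal(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float32)
        return self.network.forward(x, train=False).ravel().astype(float)


def train_head(features: np.ndarray, labels: np.ndarray, config: HeadConfig) -> TrainedHead:
    """Mini-batch Adam on the configured loss plus an L1 weight penalty.

    Dropout and batch statistics are active only during training; with a
    fixed seed the final weights are bit-reproducible.
    """
    x = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=float)
    if len(set(y.astype(int).tolist())) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    arch = head_architecture(input_dim=x.shape[1], dropout_rate=config.dropout_rate)
    net = build_network(arch, rng)
    opt = Adam(net.params, net.grads, lr=config.learning_rate)
    n = x.shape[0]
    batch = min(config.batch_size, n)
    weights = net.weight_matrices()

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = x[idx], y[idx]
            p = _clip(net.forward(xb, train=True).ravel().astype(float))
            dL_dp = _loss_grad_wrt_p(p, yb, config) / idx.size
            net.backward(dL_dp[:, None].astype(np.float32))
            if config.l1_weight > 0:
                # subgradient of l1 * sum|W| folded into the accumulated grads
                for w, g in zip(net.params, net.grads):
                    if w.ndim > 1:
                        g += config.l1_weight * np.sign(w)
            opt.step()
    return TrainedHead(net, config)


def predict_proba(model, features: np.ndarray) -> np.ndarray:
    """Probability of the abnormal class, one value per row (predictor C1)."""
    features = np.asarray(features, dtype=float)
    if hasattr(model, "predict_proba_abnormal"):
        return model.predict_proba_abnormal(features)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(features)
        col = list(model.classes_).index(1)
        return proba[:, col]
    raise TypeError(f"object {model!r} exposes no probability interface")


class _SkBaseline:
    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    def fit(self, x, y):
        self.estimator.fit(x, y)
        self.classes_ = self.estimator.classes_
        return self

    def predict_proba(self, x):
        return self.estimator.predict_proba(x)

    def predict_proba_abnormal(self, x):
        return predict_proba(self.estimator, x)


BASELINE_NAMES = ("knn", "logistic", "svm", "random_forest")


def fit_baselines(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> list[_SkBaseline]:
    """The four classical baselines, fitted, under one probability interface.

    Unstated hyperparameters default to: k=5 neighbours, RBF kernel with
    probability calibration, 100 trees; all randomness seeded.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("baselines need both classes present")
    models = [
        _SkBaseline("knn", KNeighborsClassifier(n_neighbors=min(5, len(y) - 1))),
        _SkBaseline("logistic", LogisticRegression(max_iter=1000, random_state=seed)),
        _SkBaseline("svm", CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                                  ensemble=False)),
        _SkBaseline("random_forest", RandomForestClassifier(n_estimators=100,
                                                            random_state=seed)),
    ]
    return [m.fit(x, y) for m in models]
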