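"""Score combination, threshold search, the three-level vote, and evaluation.

The two predictors are the head's abnormality probability (C1) and the
CSDAE reconstruction error (C2).  They are combined two ways:

* a linear score ``f_b(C) = C1 + b2*C2 + ... + bP*CP`` whose coefficients
  are chosen to maximize the empirical (Mann-Whitney) AUC over a grid;
* a threshold pair ``(T, P)`` — an error threshold below the mean training
  reconstruction error and a probability threshold in (0.5, 1) — scored by
  the ordinal flag count ``1[err > T] + 1[prob > P]`` and again selected by
  empirical-AUC maximization.

A panel of binary voters (baselines, head, threshold rule) then assigns
each case one of three levels: unanimous negatives are *normal*, unanimous
positives *abnormal*, and any disagreement *uncertain* — the band a
radiologist reads first.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

NORMAL, ABNORMAL, UNCERTAIN = "normal", "abnormal", "uncertain"


# ---------------------------------------------------------------------------
# empirical AUC
# ---------------------------------------------------------------------------

def empirical_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney estimate of P(score_pos > score_neg), ties credited 1/2.

    Computed from midranks in O(n log n); identical to the brute-force
    pairwise count with half-credit for ties.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty for an AUC")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _auc_of(scores: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=int)
    return empirical_auc(scores[labels == 1], scores[labels == 0])


# ---------------------------------------------------------------------------
# linear combination
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Per-case predictor values (columns C1..CP) with binary truth labels."""

    scores: np.ndarray  # (n, P)
    labels: np.ndarray  # (n,), {0,1}

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape[0] != self.labels.size:
            raise ValueError("scores and labels are misaligned")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.labels.min() == self.labels.max():
            raise ValueError("need both positive and negative cases")


@dataclass
class CombinationModel:
    beta: np.ndarray  # coefficients for C2..CP (C1 fixed at 1)
    auc: float

    def score(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores[:, 0] + scores[:, 1:] @ self.beta


def default_beta_grid() -> np.ndarray:
    """0 plus +/- 41 log-spaced magnitudes in [1e-3, 1e3].

    The wide range accommodates predictors on very different scales
    (probabilities near 1 versus reconstruction MSEs near 1e-3).
    """
    mags = np.logspace(-3, 3, 41)
    return np.concatenate([[0.0], mags, -mags])


def fit_combination(scores: ScoreMatrix, beta_grid: np.ndarray | None = None) -> CombinationModel:
    """Empirical-AUC-maximizing coefficients over a coefficient grid.

    The grid is applied per free coefficient (Cartesian product for more
    than two predictors).  Ties are broken toward the smallest coefficient
    norm, then the earliest grid-enumeration order; since the grid contains
    0, the combined AUC can never fall below the AUC of C1 alone.
    """
    grid = default_beta_grid() if beta_grid is None else np.asarray(beta_grid, float)
    if not np.any(grid == 0.0):
        raise ValueError("beta grid must include 0")
    p_free = scores.scores.shape[1] - 1
    if p_free < 1:
        raise ValueError("need at least 2 predictors to combine")
    best = None
    for enum_idx, combo in enumerate(itertools.product(grid, repeat=p_free)):
        b = np.array(combo)
        auc = _auc_of(scores.scores[:, 0] + scores.scores[:, 1:] @ b, scores.labels)
        key = (-auc, float(np.linalg.norm(b)), enum_idx)
        if best is None or key < best[0]:
            best = (key, b, auc)
    return CombinationModel(beta=best[1], auc=best[2])


# ---------------------------------------------------------------------------
# threshold rule
# ---------------------------------------------------------------------------

@dataclass
class ThresholdRule:
    """Error threshold T in (0, t_mean) and probability threshold P in (0.5, 1)."""

    t: float
    p: float
    t_mean: float
    auc: float = float("nan")

    def flags(self, prob: np.ndarray, recon_err: np.ndarray) -> np.ndarray:
        """Ordinal abnormality score in {0, 1, 2}."""
        return ((np.asarray(recon_err, float) > self.t).astype(int)
                + (np.asarray(prob, float) > self.p).astype(int))

    def votes(self, prob: np.ndarray, recon_err: np.ndarray) -> np.ndarray:
        """Binary vote: abnormal when either threshold fires."""
        return (self.flags(prob, recon_err) >= 1).astype(int)


def fit_threshold_rule(prob: np.ndarray, recon_err: np.ndarray, labels: np.ndarray,
                       t_mean: float, grid_sizes: tuple[int, int] = (25, 25)) -> ThresholdRule:
    """Grid search of (T, P) maximizing the empirical AUC of the flag count.

    Candidate thresholds are placed strictly inside the open intervals
    (0, t_mean) and (0.5, 1); ties prefer the smaller P, then the smaller T.
    """
    if t_mean <= 0:
        raise ValueError("t_mean must be positive")
    prob = np.asarray(prob, dtype=float)
    recon_err = np.asarray(recon_err, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_t, n_p = grid_sizes
    t_grid = t_mean * np.arange(1, n_t + 1) / (n_t + 1)
    p_grid = 0.5 + 0.5 * np.arange(1, n_p + 1) / (n_p + 1)
    best = None
    for p_thr in p_grid:
        p_flag = (prob > p_thr).astype(int)
        for t_thr in t_grid:
            score = (recon_err > t_thr).astype(int) + p_flag
            auc = _auc_of(score.astype(float), labels)
            key = (-auc, p_thr, t_thr)
            if best is None or key < best[0]:
                best = (key, t_thr, p_thr, auc)
    return ThresholdRule(t=float(best[1]), p=float(best[2]), t_mean=float(t_mean),
                         auc=float(best[3]))


# ---------------------------------------------------------------------------
# vote and evaluation
# ---------------------------------------------------------------------------

def triage_vote(binary_votes: np.ndarray) -> list[str]:
    """Unanimity vote over the predictor panel, one row of votes per case.

    All voters 0 -> normal; all 1 -> abnormal; any split -> uncertain.
    """
    votes = np.atleast_2d(np.asarray(binary_votes, dtype=int))
    if votes.shape[1] < 2:
        raise ValueError("vote needs at least 2 panel members")
    out = []
    for row in votes:
        if np.all(row == 0):
            out.append(NORMAL)
        elif np.all(row == 1):
            out.append(ABNORMAL)
        else:
            out.append(UNCERTAIN)
    return out


@dataclass
class EvalReport:
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    auc: float | None = None
    confusion: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall, "f1": self.f1,
             "auc": self.auc, "extra": self.extra}
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def _prf(tp: int, fp: int, fn: int, what: str) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn(f"no predicted positives for the {what} class; precision set to 0",
                      stacklevel=3)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return precision, recall, f1


def evaluate_binary(pred, truth, scores: np.ndarray | None = None) -> EvalReport:
    """Per-class precision/recall/F1, the 2x2 confusion matrix, and the AUC.

    Both the abnormal-class (positive = 1) and the normal-class rows are
    reported, mirroring the per-class presentation of screening sweeps.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size != truth.size:
        raise ValueError("prediction/truth length mismatch")
    report = EvalReport()
    # confusion[i, j] = count(truth == i, pred == j)
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(truth, pred):
        confusion[t, p] += 1
    report.confusion = confusion
    for cls, name in ((1, "abnormal"), (0, "normal")):
        tp = int(np.sum((pred == cls) & (truth == cls)))
        fp = int(np.sum((pred == cls) & (truth != cls)))
        fn = int(np.sum((pred != cls) & (truth == cls)))
        pr, rc, f1 = _prf(tp, fp, fn, name)
        report.precision[name] = pr
        report.recall[name] = rc
        report.f1[name] = f1
    if scores is not None:
        report.auc = _auc_of(np.asarray(scores, float), truth)
    return report


def evaluate_triage(triage_labels: list[str], truth) -> EvalReport:
    """Level counts plus precision within each definite level.

    Total precision pools the two definite levels: correct definite calls
    over all definite calls.  Empty levels report ``None`` (not applicable).
    """
    truth = np.asarray(truth, dtype=int)
    levels = np.asarray(triage_labels)
    counts = {lvl: int(np.sum(levels == lvl)) for lvl in (NORMAL, ABNORMAL, UNCERTAIN)}
    correct_norm = int(np.sum((levels == NORMAL) & (truth == 0)))
    correct_abn = int(np.sum((levels == ABNORMAL) & (truth == 1)))
    report = EvalReport()
    report.extra["counts"] = counts
    report.precision[NORMAL] = (correct_norm / counts[NORMAL]) if counts[NORMAL] else None
    report.precision[ABNORMAL] = (correct_abn / counts[ABNORMAL]) if counts[ABNORMAL] else None
    n_definite = counts[NORMAL] + counts[ABNORMAL]
    report.precision["total"] = ((correct_norm + correct_abn) / n_definite
                                 if n_definite else None)
    report.extra["n_definite"] = n_definite
    report.extra["uncertain_fraction"] = counts[UNCERTAIN] / truth.size if truth.size else None
    return report


def threshold_sweep(recon_err: np.ndarray, labels: np.ndarray,
                    n_points: int = 50) -> dict[str, np.ndarray]:
    """Precision/recall of the rule ``error > t`` across the error range."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    recon_err = np.asarray(recon_err, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.linspace(recon_err.min(), recon_err.max(), n_points)
    precisions, recalls = [], []
    n_pos = int(labels.sum())
    for t in thresholds:
        pred = recon_err > t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precisions.append(tp / (tp + fp) if tp + fp else np.nan)
        recalls.append(tp / n_pos if n_pos else np.nan)
    return {"threshold": thresholds,
            "precision": np.array(precisions),
            "recall": np.array(recalls)}
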