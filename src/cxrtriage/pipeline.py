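"""End-to-end triage pipeline: preprocess -> segment -> features/classify ->
autoencoder -> combine/decide -> evaluate.

One global seed deterministically derives every stage seed (CRC32 of the
stage name XOR-mixed with the global seed, reduced below 2**31), so a rerun
with the same configuration reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combine as cmb
from .autoencoder import TrainConfig, reconstruction_errors, train_autoencoder
from .classifier import HeadConfig, fit_baselines, predict_proba, train_head
from .features import NormalizationStats, extract_features, rebalance
from .lung import crop_to_mask_bbox, segment_lungs_fallback
from .manifest import load_image, load_mask, read_manifest, write_report
from .preprocess import AugmentSpec, SplitSpec, augment, equalize_histogram, resize

log = logging.getLogger("cxrtriage")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2 ** 31)


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    side: int = 64
    seed: int = 0
    train_fraction: float = 0.7
    extractor: str = "builtin"
    balance: str = "none"  # none | smote | smote_tk | smote_enn
    augment_mode: str = "none"  # none | positive | 4x
    csdae_epochs: int = 30
    csdae_noise: float = 0.01
    head_epochs: int = 60
    head_loss: str = "focal"
    threshold_grid: tuple[int, int] = (25, 25)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    out_dir: Path
    triage: pd.DataFrame
    scores: pd.DataFrame
    binary_report: cmb.EvalReport
    triage_report: cmb.EvalReport
    combination: cmb.CombinationModel
    rule: cmb.ThresholdRule


def _preprocess_case(record, side: int) -> tuple[np.ndarray, np.ndarray]:
    img = load_image(record.path)
    img = equalize_histogram(img)
    mask = load_mask(record.mask_path) if record.mask_path else segment_lungs_fallback(img)
    cropped = crop_to_mask_bbox(img, mask)
    return resize(cropped, side), mask


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all artifacts to ``out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(config.to_dict(), out_dir / "run_config.json")

    def _stage(name: str) -> np.random.Generator:
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        return np.random.default_rng(stage_seed(config.seed, name))

    # -- load & preprocess -------------------------------------------------
    _stage("load")
    records = read_manifest(config.manifest)
    images: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for rec in records:
        try:
            images[rec.case_id], _ = _preprocess_case(rec, config.side)
        except Exception as exc:  # noqa: BLE001 - stage context per contract
            raise RuntimeError(f"stage preprocess failed on case {rec.case_id}: {exc}") from exc
        labels[rec.case_id] = rec.label

    # -- split -------------------------------------------------------------
    _stage("split")
    ids = [r.case_id for r in records]
    from .preprocess import split_dataset
    train_ids, test_ids = split_dataset(ids, SplitSpec(config.train_fraction,
                                                       stage_seed(config.seed, "split")))
    pd.DataFrame({"case_id": train_ids + test_ids,
                  "partition": ["train"] * len(train_ids) + ["test"] * len(test_ids)}
                 ).to_csv(out_dir / "split.csv", index=False)

    # -- augmentation (training images only) --------------------------------
    aug_rng = _stage("augment")
    aug_images: list[np.ndarray] = []
    aug_labels: list[int] = []
    if config.augment_mode != "none":
        spec = AugmentSpec()
        for cid in train_ids:
            if config.augment_mode == "positive" and labels[cid] != 1:
                continue
            n_copies = 3 if config.augment_mode == "4x" else 1
            for _ in range(n_copies):
                aug_images.append(augment(images[cid], spec, aug_rng))
                aug_labels.append(labels[cid])

    # -- features ----------------------------------------------------------
    _stage("features")
    feat = {cid: extract_features(images[cid], config.extractor) for cid in ids}
    x_train = np.array([feat[c] for c in train_ids])
    y_train = np.array([labels[c] for c in train_ids])
    if aug_images:
        x_train = np.vstack([x_train, [extract_features(im, config.extractor)
                                       for im in aug_images]])
        y_train = np.concatenate([y_train, aug_labels])
    x_test = np.array([feat[c] for c in test_ids])
    y_test = np.array([labels[c] for c in test_ids])

    stats = NormalizationStats(x_train)
    x_train_n, x_test_n = stats.apply(x_train), stats.apply(x_test)
    bal_rng = _stage("rebalance")
    x_fit, y_fit = rebalance(x_train_n, y_train, config.balance, rng=bal_rng)

    # -- classifier branch ---------------------------------------------------
    _stage("classifier")
    head = train_head(x_fit, y_fit, HeadConfig(loss=config.head_loss,
                                               epochs=config.head_epochs,
                                               seed=stage_seed(config.seed, "head")))
    baselines = fit_baselines(x_fit, y_fit, seed=stage_seed(config.seed, "baselines"))
    prob_test = predict_proba(head, x_test_n)
    prob_train = predict_proba(head, x_train_n[:len(train_ids)])

    # -- autoencoder branch (trained on normal training films only) ---------
    _stage("csdae")
    normal_train = np.array([images[c] for c in train_ids if labels[c] == 0])
    state = train_autoencoder(normal_train, TrainConfig(
        epochs=config.csdae_epochs, noise_factor=config.csdae_noise,
        seed=stage_seed(config.seed, "csdae")))
    err_train_normal = reconstruction_errors(state, normal_train)
    err_test = reconstruction_errors(state, np.array([images[c] for c in test_ids]))
    err_train = reconstruction_errors(state, np.array([images[c] for c in train_ids]))
    t_mean = float(err_train_normal.mean())

    # -- combine & decide ----------------------------------------------------
    _stage("combine")
    combo = cmb.fit_combination(cmb.ScoreMatrix(
        np.column_stack([prob_train, err_train]), np.array([labels[c] for c in train_ids])))
    rule = cmb.fit_threshold_rule(prob_train, err_train,
                                  np.array([labels[c] for c in train_ids]),
                                  t_mean=t_mean, grid_sizes=config.threshold_grid)

    panel_votes = [ (predict_proba(m, x_test_n) > 0.5).astype(int) for m in baselines ]
    panel_votes.append((prob_test > 0.5).astype(int))
    panel_votes.append(rule.votes(prob_test, err_test))
    votes = np.column_stack(panel_votes)
    levels = cmb.triage_vote(votes)

    # -- evaluate & persist --------------------------------------------------
    _stage("evaluate")
    scores_df = pd.DataFrame({"case_id": test_ids, "prob": prob_test,
                              "recon_error": err_test, "label": y_test})
    scores_df.to_csv(out_dir / "scores.csv", index=False, float_format="%.10g")
    triage_df = pd.DataFrame({"case_id": test_ids, "level": levels,
                              "prob": prob_test, "recon_error": err_test})
    triage_df.to_csv(out_dir / "triage.csv", index=False, float_format="%.10g")

    binary_report = cmb.evaluate_binary((prob_test > 0.5).astype(int), y_test,
                                        scores=combo.score(
                                            np.column_stack([prob_test, err_test])))
    triage_report = cmb.evaluate_triage(levels, y_test)
    write_report({"binary": binary_report.to_dict(),
                  "triage": triage_report.to_dict(),
                  "combination": {"beta": combo.beta.tolist(), "train_auc": combo.auc},
                  "threshold_rule": {"t": rule.t, "p": rule.p, "t_mean": rule.t_mean,
                                     "train_auc": rule.auc,
                                     "score": "flag count 1[err>T] + 1[prob>P]"}},
                 out_dir / "report.json")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return RunResult(out_dir=out_dir, triage=triage_df, scores=scores_df,
                     binary_report=binary_report, triage_report=triage_report,
                     combination=combo, rule=rule)
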