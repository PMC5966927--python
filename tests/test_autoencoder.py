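"""CSDAE training, corruption, losses, reconstruction error, AE comparison."""

import numpy as np
import pytest

from cxrtriage import (PhantomConfig, TrainConfig, compare_ae_csdae, corrupt,
                       generate_dataset, reconstruction_error,
                       reconstruction_errors, reconstruction_loss,
                       train_autoencoder)
from cxrtriage.autoencoder import NetworkState, _bottleneck, _to_batch
from cxrtriage.architecture import csdae_architecture
from cxrtriage.nn import build_network


def _phantom_stack(n, size=32, abnormal=0, contrast=0.5, seed=0):
    cfg = PhantomConfig(image_size=size, n_normal=n, n_abnormal=abnormal,
                        lesion_contrast=contrast, seed=seed)
    cases = generate_dataset(cfg)
    return (np.array([c.image for c in cases if c.label == 0]),
            np.array([c.image for c in cases if c.label == 1]))


@pytest.fixture(scope="module")
def tiny_state():
    """One small trained CSDAE reused across read-only assertions."""
    normals, _ = _phantom_stack(24, size=32, seed=5)
    return train_autoencoder(normals, TrainConfig(epochs=8, batch_size=12, seed=1)), normals


class TestCorrupt:
    def test_zero_factor_is_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(corrupt(img, 0.0, rng), img)

    def test_noise_variance_matches_factor(self, rng):
        img = np.full((128, 128), 0.5)  # interior values: no clipping
        out = corrupt(img, 0.05, rng)
        var = np.var(out - img)
        assert abs(var - 0.0025) <= 0.2 * 0.0025

    def test_output_clipped(self, rng):
        out = corrupt(np.ones((64, 64)), 0.5, rng)
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_negative_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            corrupt(np.zeros((4, 4)), -0.1, rng)


class TestLoss:
    def test_perfect_reconstruction_zero(self, tiny_state):
        state, _ = tiny_state
        x = np.random.default_rng(0).random((2, 32, 32))
        cfg = TrainConfig(sparsity_weight=0.0, weight_decay=0.0)
        assert reconstruction_loss(x, x, state, cfg) == 0.0

    def test_single_pixel_half_factor(self, tiny_state):
        state, _ = tiny_state
        cfg = TrainConfig(sparsity_weight=0.0, weight_decay=0.0)
        # single pixel x=1, y=0 with no regularization: 1/2 * (1-0)^2
        got = reconstruction_loss(np.ones((1, 1)), np.zeros((1, 1)), state, cfg)
        assert got == 0.5

    def test_term_by_term_summation_oracle(self, tiny_state):
        """Full cost matches an independent elementwise summation at 1e-10."""
        state, _ = tiny_state
        rng = np.random.default_rng(3)
        x = rng.random((4, 32, 32))
        y = rng.random((4, 32, 32))
        cfg = TrainConfig(sparsity_weight=1e-5, weight_decay=1e-4)
        got = reconstruction_loss(x, y, state, cfg)
        # oracle: explicit loops over terms
        err = 0.0
        for xi, yi in zip(x, y):
            err += ((xi - yi) ** 2).sum()
        err = 0.5 * err / x.size
        wsum = sum(float((w ** 2).sum()) for w in state.network.weight_matrices())
        a = _bottleneck(state.network, _to_batch(x))
        sparse = float(np.abs(a).sum()) / 4
        expected = err + 0.5 * 1e-4 * wsum + 1e-5 * sparse
        assert got == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch_rejected(self, tiny_state):
        state, _ = tiny_state
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 32, 32)), np.zeros((2, 16, 16)),
                                state, TrainConfig())


class TestTraining:
    def test_loss_decreases_and_is_finite(self, tiny_state):
        state, _ = tiny_state
        hist = state.loss_history
        assert np.all(np.isfinite(hist))
        # few optimizer steps at this desk scale: expect a clear monotone
        # trend, not full convergence (see docs/methods.md)
        assert hist[-1] < hist[0]
        assert np.mean(np.diff(hist) < 0) > 0.6

    def test_identical_seeds_identical_histories(self):
        normals, _ = _phantom_stack(10, size=32, seed=2)
        cfg = TrainConfig(epochs=2, batch_size=10, seed=9)
        h1 = train_autoencoder(normals, cfg).loss_history
        h2 = train_autoencoder(normals, cfg).loss_history
        assert h1 == h2

    def test_reconstruction_error_basics(self, tiny_state):
        state, normals = tiny_state
        err = reconstruction_error(state, normals[0])
        assert err >= 0.0
        errs = reconstruction_errors(state, normals[:4])
        assert errs.shape == (4,)
        assert errs[0] == pytest.approx(err, rel=1e-5)
        with pytest.raises(ValueError):
            reconstruction_error(state, np.zeros((64, 64)))

    def test_anomaly_scores_rank_lesions_higher(self):
        """Trained on normals only, abnormal films score higher on average."""
        cfg = PhantomConfig(image_size=32, n_normal=40, n_abnormal=15,
                            lesion_contrast=0.5, seed=8)
        cases = generate_dataset(cfg)
        normals = np.array([c.image for c in cases if c.label == 0])
        abnormals = np.array([c.image for c in cases if c.label == 1])
        state = train_autoencoder(normals[:30], TrainConfig(epochs=10, batch_size=30, seed=0))
        e_norm = reconstruction_errors(state, normals[30:])
        e_abn = reconstruction_errors(state, abnormals)
        assert e_abn.mean() > e_norm.mean()


class TestCompare:
    def test_report_structure_and_noise_tendencies(self):
        normals, _ = _phantom_stack(20, size=32, seed=4)
        report = compare_ae_csdae(normals[:12], normals[12:], noise_factors=(0.05,),
                                  epochs=4, seed=0)
        assert set(report) == {("AE", 0.05), ("CSDAE", 0.05)}
        for entry in report.values():
            assert set(entry) == {"train", "test", "test_noised"}
            for stats in entry.values():
                assert stats["std"] >= 0.0 and np.isfinite(stats["mean"])
        # noise hurts the plain AE's reconstruction of the test set
        ae = report[("AE", 0.05)]
        assert ae["test_noised"]["mean"] >= ae["test"]["mean"]

    def test_csdae_tendency_over_seeds(self):
        """The denoising model tends to match or beat the plain AE on clean test MSE."""
        wins = 0
        for seed in range(3):
            normals, _ = _phantom_stack(24, size=32, seed=20 + seed)
            report = compare_ae_csdae(normals[:16], normals[16:], noise_factors=(0.05,),
                                      epochs=6, seed=seed)
            if (report[("CSDAE", 0.05)]["test"]["mean"]
                    <= report[("AE", 0.05)]["test"]["mean"] * 1.02):
                wins += 1
        assert wins >= 2
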