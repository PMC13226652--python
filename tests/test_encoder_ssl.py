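"""Encoder, NT-Xent objective, schedule, and pretraining loop."""

import numpy as np
import pytest

from magcardia import nn
from magcardia.augmentations import AugmentationConfig
from magcardia.encoder_ssl import (EncoderConfig, MCGEncoder, PretrainConfig,
                                   ProjectionHead, cosine_lr, encode_segments,
                                   load_checkpoint, nt_xent_loss, pretrain,
                                   save_checkpoint)
from magcardia.preprocess import Segment

TINY = EncoderConfig(widths=(4, 8), kernels=(8, 5), strides=(8, 2),
                     embed_dim=16, proj_hidden=16, proj_dim=8)


def _segments(n, rng, label=0):
    segs = []
    for i in range(n):
        sig = rng.standard_normal((64, 5000)).astype(np.float32)
        segs.append(Segment(signal=sig, fs=500, patient_id=f"p{i}",
                            segment_index=0, valid_channels=np.ones(64, bool),
                            labels={"lcx": label}))
    return segs


def brute_force_nt_xent(z, tau):
    """Independent oracle: direct softmax evaluation per anchor."""
    z = np.asarray(z, float)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    n = z.shape[0]
    B = n // 2
    total = 0.0
    for i in range(n):
        j = i + B if i < B else i - B
        num = np.exp(z[i] @ z[j] / tau)
        den = sum(np.exp(z[i] @ z[k] / tau) for k in range(n) if k != i)
        total += -np.log(num / den)
    return total / n


class TestNtXent:
    def test_identical_projections_give_ln3(self):
        z = np.ones((4, 8))
        assert nt_xent_loss(z, 0.1) == pytest.approx(np.log(3), abs=1e-12)

    def test_orthogonal_pairs_brute_force_value(self):
        # pairs identical within, orthogonal across, tau = 0.1
        z = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], float)
        expected = -np.log(np.exp(10) / (np.exp(10) + 2 * np.exp(0)))
        assert nt_xent_loss(z, 0.1) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(9.08e-5, rel=0.01)

    @pytest.mark.parametrize("B", [2, 3, 4])
    def test_matches_brute_force_oracle(self, B, rng):
        z = rng.standard_normal((2 * B, 16))
        assert nt_xent_loss(z, 0.2) == pytest.approx(
            brute_force_nt_xent(z, 0.2), abs=1e-9)

    def test_pair_order_permutation_invariance(self, rng):
        z = rng.standard_normal((8, 6))
        perm = np.array([2, 0, 3, 1])
        zp = np.concatenate([z[:4][perm], z[4:][perm]])
        assert nt_xent_loss(zp, 0.15) == pytest.approx(
            nt_xent_loss(z, 0.15), abs=1e-12)

    def test_loss_is_strictly_positive(self, rng):
        for _ in range(5):
            assert nt_xent_loss(rng.standard_normal((6, 10)), 0.1) > 0.0

    def test_loss_decreases_with_temperature_on_a_random_batch(self, rng):
        # for random projections some negatives outrank the positive, so a
        # sharper softmax (smaller tau) inflates the loss; it relaxes toward
        # log(2B-1) as tau grows
        z = rng.standard_normal((8, 16))
        losses = [nt_xent_loss(z, tau) for tau in (0.05, 0.1, 0.2, 0.5)]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert all(l > np.log(7) - 1e-9 for l in losses)

    def test_too_few_projections_rejected(self):
        with pytest.raises(ValueError):
            nt_xent_loss(np.ones((2, 4)), 0.1)

    def test_gradient_matches_finite_differences(self, rng):
        z = rng.standard_normal((6, 5))
        _, dz = nt_xent_loss(z, 0.3, return_grad=True)
        eps = 1e-6
        for i, j in [(0, 0), (2, 3), (5, 4)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (nt_xent_loss(zp, 0.3) - nt_xent_loss(zm, 0.3)) / (2 * eps)
            assert dz[i, j] == pytest.approx(num, abs=1e-6)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0) == pytest.approx(1e-3, rel=1e-12)
        assert cosine_lr(100) == pytest.approx(1e-5, rel=1e-12)
        assert cosine_lr(50) == pytest.approx(5.05e-4, rel=1e-12)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(101)
        with pytest.raises(ValueError):
            cosine_lr(-1)


class TestEncoder:
    def test_zero_segment_gives_finite_embedding(self):
        enc = MCGEncoder(TINY, np.random.default_rng(0))
        emb = enc.forward(np.zeros((1, 64, 5000), np.float32), train=False)
        assert emb.shape == (1, 16)
        assert np.isfinite(emb).all()

    def test_inference_is_deterministic(self, rng):
        enc = MCGEncoder(TINY, np.random.default_rng(0))
        x = rng.standard_normal((2, 64, 5000)).astype(np.float32)
        assert np.array_equal(enc.forward(x, train=False),
                              enc.forward(x, train=False))

    def test_single_sample_perturbation_changes_the_embedding(self, rng):
        enc = MCGEncoder(TINY, np.random.default_rng(0))
        x = rng.standard_normal((1, 64, 5000)).astype(np.float32)
        x2 = x.copy()
        x2[0, 10, 2500] += 5.0
        e1, e2 = enc.forward(x, train=False), enc.forward(x2, train=False)
        assert np.isfinite(e2).all() and not np.array_equal(e1, e2)

    def test_wrong_shape_rejected(self):
        enc = MCGEncoder(TINY, np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc.forward(np.zeros((1, 32, 5000), np.float32))

    def test_backprop_matches_directional_finite_difference(self, rng):
        """Full-network gradient check with a quadratic readout loss."""
        cfg = EncoderConfig(widths=(4, 4), kernels=(8, 5), strides=(8, 2),
                            embed_dim=8, proj_hidden=8, proj_dim=8,
                            normalize_input=False)
        enc = MCGEncoder(cfg, np.random.default_rng(1))
        x = (0.5 * rng.standard_normal((3, 64, 5000))).astype(np.float32)
        params = enc.params()

        def loss():
            e = enc.forward(x, train=True)
            return 0.5 * float((e.astype(np.float64) ** 2).sum()), e

        _, e = loss()
        for p in params:
            p.zero_grad()
        enc.backward(e)
        gn = np.sqrt(sum(float((p.g ** 2).sum()) for p in params))
        dirs = [(p.g / gn).copy() for p in params]
        eps = 1e-3
        for p, d in zip(params, dirs):
            p.v += (eps * d).astype(np.float32)
        lp, _ = loss()
        for p, d in zip(params, dirs):
            p.v -= (2 * eps * d).astype(np.float32)
        lm, _ = loss()
        assert (lp - lm) / (2 * eps) == pytest.approx(gn, rel=1e-3)


class TestPretrain:
    def _run(self, seed=3):
        rng = np.random.default_rng(0)
        segs = _segments(12, rng)
        cfg = PretrainConfig(epochs=3, batch_size=6, seed=seed,
                             augment=AugmentationConfig())
        return pretrain(segs, TINY, cfg), segs

    def test_loss_decreases_on_synthetic_data(self):
        result, _ = self._run()
        assert result.loss_trace[-1] < result.loss_trace[0]

    def test_same_seed_gives_identical_loss_traces(self):
        r1, _ = self._run()
        r2, _ = self._run()
        assert r1.loss_trace == r2.loss_trace

    def test_views_of_same_segment_more_aligned_than_cross_segment(self):
        result, segs = self._run()
        rng = np.random.default_rng(55)
        cfg = AugmentationConfig()
        from magcardia.augmentations import make_views
        embs1, embs2 = [], []
        for s in segs:
            a, b = make_views(s.signal, cfg, rng)
            embs1.append(result.encoder.forward(a[None], train=False)[0])
            embs2.append(result.encoder.forward(b[None], train=False)[0])
        e1 = np.stack(embs1)
        e2 = np.stack(embs2)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        sims = e1 @ e2.T
        same = np.diag(sims).mean()
        cross = sims[~np.eye(len(segs), dtype=bool)].mean()
        assert same > cross

    def test_checkpoint_round_trip_preserves_embeddings(self, tmp_path):
        result, segs = self._run()
        save_checkpoint(tmp_path / "ckpt", result)
        loaded = load_checkpoint(tmp_path / "ckpt")
        probe = segs[:4]
        assert np.array_equal(encode_segments(result.encoder, probe),
                              encode_segments(loaded.encoder, probe))
        assert loaded.loss_trace == result.loss_trace

    def test_fewer_than_two_segments_rejected(self):
        with pytest.raises(ValueError):
            pretrain([], TINY, PretrainConfig(epochs=1))
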