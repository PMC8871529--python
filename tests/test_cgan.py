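"""pix2pix components: backprop correctness, loss forms, training contracts."""

import dataclasses

import numpy as np
import pytest

from tomodose.cgan import (
    Checkpoint,
    PairedDataset,
    TrainConfig,
    UNetGenerator,
    apply_generator,
    build_models,
    d_loss,
    denoise,
    g_adv_loss,
    gan_losses,
    l1_loss,
    select_epoch,
    train,
)
from tomodose.cgan.models import PatchDiscriminator
from tomodose.cgan.nn import Adam, Conv2d, InstanceNorm2d, Param, UpsampleNearest2


def _numeric_grad(loss_fn, param_array, idx, eps=1e-6):
    orig = param_array[idx]
    param_array[idx] = orig + eps
    lp = loss_fn()
    param_array[idx] = orig - eps
    lm = loss_fn()
    param_array[idx] = orig
    return (lp - lm) / (2 * eps)


class TestBackpropCorrectness:
    """Every analytic gradient is checked against central differences."""

    def test_conv2d_gradients(self, rng):
        conv = Conv2d(2, 3, 3, stride=2, pad=1, rng=rng, dtype=np.float64)
        x = rng.random((2, 8, 8))
        tgt = rng.random((3, 4, 4))

        def loss_fn():
            return float(((conv.forward(x) - tgt) ** 2).mean())

        out = conv.forward(x)
        conv.w.grad[...] = 0
        conv.b.grad[...] = 0
        dx = conv.backward(2 * (out - tgt) / out.size)
        for arr, grads in ((conv.w.value, conv.w.grad), (conv.b.value, conv.b.grad)):
            flat, gflat = arr.ravel(), grads.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                assert gflat[i] == pytest.approx(
                    _numeric_grad(loss_fn, flat, i), abs=1e-8, rel=1e-5
                )
        i = (1, 3, 5)
        assert dx[i] == pytest.approx(_numeric_grad(loss_fn, x, i), abs=1e-8, rel=1e-5)

    def test_instance_norm_gradients(self, rng):
        norm = InstanceNorm2d(2, dtype=np.float64)
        norm.gamma.value[:] = rng.random(2) + 0.5
        x = rng.random((2, 5, 5))
        tgt = rng.random((2, 5, 5))

        def loss_fn():
            return float(((norm.forward(x) - tgt) ** 2).mean())

        out = norm.forward(x)
        norm.gamma.grad[...] = 0
        norm.beta.grad[...] = 0
        dx = norm.backward(2 * (out - tgt) / out.size)
        i = (0, 2, 3)
        assert dx[i] == pytest.approx(_numeric_grad(loss_fn, x, i), abs=1e-8, rel=1e-4)
        assert norm.gamma.grad[1] == pytest.approx(
            _numeric_grad(loss_fn, norm.gamma.value, 1), abs=1e-8, rel=1e-5
        )

    def test_upsample_adjointness(self, rng):
        up = UpsampleNearest2()
        x = rng.random((1, 4, 4))
        y = rng.random((1, 8, 8))
        # <Ux, y> == <x, U^T y>
        lhs = float((up.forward(x) * y).sum())
        rhs = float((x * up.backward(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_generator_end_to_end_gradients(self, rng):
        gen = UNetGenerator(base_channels=3, depth=2, dropout_p=0.0, rng=rng,
                            dtype=np.float64)
        x = rng.random((1, 8, 8))
        tgt = rng.random((1, 8, 8))

        def loss_fn():
            return float(((gen.forward(x) - tgt) ** 2).mean())

        out = gen.forward(x)
        for p in gen.params():
            p.grad[...] = 0
        gen.backward(2 * (out - tgt) / out.size)
        checked = 0
        for p in gen.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                assert gflat[i] == pytest.approx(
                    _numeric_grad(loss_fn, flat, i), abs=1e-8, rel=1e-4
                )
                checked += 1
        assert checked >= 20

    def test_discriminator_end_to_end_gradients(self, rng):
        disc = PatchDiscriminator(base_channels=3, rng=rng, dtype=np.float64)
        a, b = rng.random((1, 16, 16)), rng.random((1, 16, 16))

        def loss_fn():
            logits = disc.forward_logits(a, b)
            return float(-np.log(1.0 / (1.0 + np.exp(-logits))).mean())

        logits = disc.forward_logits(a, b)
        p = 1.0 / (1.0 + np.exp(-logits))
        for q in disc.params():
            q.grad[...] = 0
        disc.backward_logits((p - 1.0) / p.size)
        for q in disc.params():
            flat, gflat = q.value.ravel(), q.grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                assert gflat[i] == pytest.approx(
                    _numeric_grad(loss_fn, flat, i), abs=1e-8, rel=1e-4
                )


class TestModelContracts:
    def test_generator_preserves_shape(self, rng):
        gen, _ = build_models(TrainConfig(seed=0, gen_base_channels=4))
        x = rng.random((1, 64, 64)).astype(np.float32)
        out = gen.forward(x)
        assert out.shape == (1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_discriminator_score_map_smaller_than_image(self, rng):
        _, disc = build_models(TrainConfig(seed=0, gen_base_channels=4))
        score = disc.forward(rng.random((1, 64, 64)), rng.random((1, 64, 64)))
        assert score.shape[1] < 64 and score.shape[2] < 64
        assert (score > 0).all() and (score < 1).all()

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_models(TrainConfig(patch_px=50))

    def test_seeded_init_reproducible(self):
        cfg = TrainConfig(seed=5, gen_base_channels=4)
        g1, _ = build_models(cfg, np.random.default_rng(5))
        g2, _ = build_models(cfg, np.random.default_rng(5))
        for p1, p2 in zip(g1.params(), g2.params()):
            assert np.array_equal(p1.value, p2.value)


class TestLosses:
    def test_half_probability_discriminator_closed_form(self):
        half = np.full((1, 4, 4), 0.5)
        assert d_loss(half, half) == pytest.approx(2.0 * np.log(2.0), abs=1e-9)

    def test_perfect_generator_zero_l1(self, rng):
        pref = rng.random((1, 8, 8))
        assert l1_loss(pref, pref.copy()) == 0.0

    def test_alpha_zero_reduces_to_adversarial(self, rng):
        cfg = TrainConfig(seed=0, gen_base_channels=4)
        gen, disc = build_models(cfg, np.random.default_rng(0))
        pld = rng.random((1, 16, 16)).astype(np.float32)
        pref = rng.random((1, 16, 16)).astype(np.float32)
        rng_state = np.random.default_rng(1)
        # same dropout draw for both evaluations
        for blk in gen.dec:
            for lay in blk.layers:
                if lay.__class__.__name__ == "Dropout":
                    lay.p = 0.0
        _, g_only_adv = gan_losses(disc, gen, pld, pref, alpha_l1=0.0)
        fake = gen.forward(pld)
        expected = g_adv_loss(disc.forward(pld, fake))
        assert g_only_adv == pytest.approx(expected, rel=1e-6)

    def test_probabilities_outside_unit_interval_rejected(self):
        bad = np.array([[0.0, 0.5]])
        with pytest.raises(ValueError, match="inside"):
            d_loss(bad, bad)
        with pytest.raises(ValueError):
            g_adv_loss(np.array([[1.0]]))


def _noise_pairs(rng, n, size=32, noise=0.05):
    """Textured reference images (smoothed random fields) plus noisy copies."""
    from scipy.ndimage import gaussian_filter

    pairs = []
    for _ in range(n):
        field = gaussian_filter(rng.standard_normal((size, size)), 3.0)
        field = field / max(field.std(), 1e-9) * 0.12
        ref = np.clip(0.5 + field, 0, 1).astype(np.float32)
        low = np.clip(ref + rng.normal(0, noise, ref.shape), 0, 1).astype(np.float32)
        pairs.append((low, ref))
    return pairs


class TestTraining:
    def test_checkpoint_cadence(self, rng):
        cfg = TrainConfig(epochs=6, checkpoint_every=2, seed=0,
                          gen_base_channels=4, patch_px=16)
        ckpts, curve = train(PairedDataset(_noise_pairs(rng, 4, 16)), cfg)
        assert list(curve["epoch"]) == [2, 4, 6]
        assert [c.epoch for c in ckpts] == [2, 4, 6]

    def test_validation_error_improves(self, rng):
        cfg = TrainConfig(epochs=20, checkpoint_every=1, seed=3,
                          gen_base_channels=4, patch_px=32)
        ckpts, curve = train(PairedDataset(_noise_pairs(rng, 12, 32)), cfg)
        assert curve["mse"].iloc[-1] < curve["mse"].iloc[0]

    def test_identity_dataset_beats_constant_predictor(self, rng):
        pairs = [(p[1], p[1]) for p in _noise_pairs(rng, 8, 32)]
        cfg = TrainConfig(epochs=15, checkpoint_every=5, seed=2,
                          gen_base_channels=4, patch_px=32)
        ckpts, curve = train(PairedDataset(pairs), cfg)
        const_mse = float(np.mean((pairs[0][1] - 0.5) ** 2))
        assert curve["mse"].min() < const_mse

    def test_training_reproducible(self, rng):
        pairs = _noise_pairs(rng, 4, 16)
        cfg = TrainConfig(epochs=3, checkpoint_every=1, seed=11,
                          gen_base_channels=4, patch_px=16)
        _, c1 = train(PairedDataset([(a.copy(), b.copy()) for a, b in pairs]), cfg)
        _, c2 = train(PairedDataset(pairs), cfg)
        assert np.array_equal(c1[["mse", "mssim"]].values, c2[["mse", "mssim"]].values)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="training pair"):
            train(PairedDataset([], split=[]), TrainConfig(epochs=1))


class TestEpochSelection:
    def _curve(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["epoch", "mse", "mssim"])

    def test_agreeing_optima(self):
        curve = self._curve([(100, 0.5, 0.8), (200, 0.3, 0.85), (300, 0.1, 0.9)])
        assert select_epoch(curve) == 300

    def test_single_row(self):
        assert select_epoch(self._curve([(40, 0.2, 0.7)])) == 40

    def test_rank_tie_prefers_later_epoch(self):
        curve = self._curve([(80, 0.1, 0.80), (90, 0.2, 0.90)])
        assert select_epoch(curve) == 90

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_epoch(self._curve([]))


class TestInference:
    def test_denoise_preserves_shapes_and_metadata(self, bench, rng):
        from tomodose.pipeline import noisy_normalized
        from tomodose.acquisition import DoseLevel

        gen, _ = build_models(TrainConfig(seed=0, gen_base_channels=4))
        low = noisy_normalized(bench.noiseless, DoseLevel("reduce50", 0.49), 5, 5.0, 4.0)
        out = denoise(low, gen)
        assert out.images.shape == low.images.shape
        assert out.arm == "pix2pix"
        assert out.dose_factor == low.dose_factor
        assert out.images.min() >= 0.0 and out.images.max() <= 1.0

    def test_tiled_equals_direct_on_smooth_generator(self, rng):
        # untrained generator is a fixed smooth map; tiling must blend
        # without seams large relative to the map's own variation
        gen = UNetGenerator(base_channels=4, depth=2, dropout_p=0.0,
                            rng=np.random.default_rng(0))
        img = rng.random((96, 96)).astype(np.float32)
        out = apply_generator(gen, img)
        assert out.shape == img.shape

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = TrainConfig(epochs=1, checkpoint_every=1, seed=1,
                          gen_base_channels=4, patch_px=16)
        ckpts, _ = train(PairedDataset(_noise_pairs(rng, 2, 16)), cfg)
        path = tmp_path / "ckpt.npz"
        ckpts[-1].save(path)
        loaded = Checkpoint.load(path)
        assert loaded.epoch == ckpts[-1].epoch
        for a, b in zip(loaded.weights, ckpts[-1].weights):
            assert np.array_equal(a, b)

    def test_checkpoint_config_mismatch_rejected(self, rng):
        cfg = TrainConfig(epochs=1, checkpoint_every=1, seed=1,
                          gen_base_channels=4, patch_px=16)
        ckpts, _ = train(PairedDataset(_noise_pairs(rng, 2, 16)), cfg)
        bad = Checkpoint(1, dataclasses.replace(cfg, gen_base_channels=8),
                         ckpts[-1].weights)
        with pytest.raises(ValueError, match="mismatch"):
            bad.build_generator()
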