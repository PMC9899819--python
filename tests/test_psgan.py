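"""Tests of the enhancement GAN: losses, reductions, training contracts."""

import numpy as np
import pytest

from octaclear.nn.tensor import Tensor
from octaclear.psgan import (
    BaselineWeights,
    EnhanceWeights,
    LinearFeatureExtractor,
    PSGANConfig,
    baseline_loss,
    build_extractor,
    build_psgan,
    cyclic_perceptual_loss,
    enhance,
    load_psgan,
    psgan_loss,
    save_psgan,
    structure_loss,
    train_psgan,
)
from octaclear.synthetic import generate_vessel_phantom, reduce_contrast


@pytest.fixture(scope="module")
def tiny_models():
    return build_psgan(PSGANConfig.tiny(seed=3))


@pytest.fixture(scope="module")
def pools():
    xs = [reduce_contrast(generate_vessel_phantom(i, 64, 64)[0], 0.4) for i in range(4)]
    ys = [generate_vessel_phantom(100 + i, 64, 64)[0] for i in range(4)]
    return xs, ys


class _IdentityGen:
    def __call__(self, x):
        return x


class TestBuild:
    def test_generator_shape_and_identity_at_init(self, tiny_models, rng):
        x = rng.random((1, 1, 64, 64))
        out = tiny_models.g_xy(Tensor(x))
        assert out.data.shape == x.shape
        # zero-initialized residual branch: exact identity on [0, 1] inputs
        np.testing.assert_array_equal(out.data, x)

    def test_discriminator_finite_score_map(self, tiny_models, rng):
        score = tiny_models.d_x(Tensor(rng.random((1, 1, 64, 64))))
        assert np.all(np.isfinite(score.data))
        assert score.data.shape[2] < 64

    def test_seeded_builds_identical(self):
        cfg = PSGANConfig.tiny(seed=9)
        a = build_psgan(cfg)
        b = build_psgan(cfg)
        for ma, mb in zip(a, b):
            for pa, pb in zip(ma.params(), mb.params()):
                assert np.array_equal(pa.data, pb.data)

    def test_odd_image_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            build_psgan(PSGANConfig.tiny(image_size=63))


class TestBaselineLoss:
    def test_identity_generators_zero_cycle_and_identity(self, tiny_models, rng):
        x = rng.random((1, 1, 64, 64))
        y = rng.random((1, 1, 64, 64))
        _, bd = baseline_loss(Tensor(x), Tensor(y), tiny_models)
        # freshly built generators are identity maps
        assert bd["cycle"] == pytest.approx(0.0, abs=1e-12)
        assert bd["identity"] == pytest.approx(0.0, abs=1e-12)

    def test_weight_masking_leaves_adversarial_only(self, tiny_models, rng):
        x, y = rng.random((2, 1, 1, 64, 64))
        bw = BaselineWeights(lambda_cyc=0.0, lambda_idt=0.0)
        total, bd = baseline_loss(Tensor(x), Tensor(y), tiny_models, bw)
        assert float(total.data) == pytest.approx(bd["adv_xy"] + bd["adv_yx"], abs=1e-9)

    def test_linear_combination_oracle(self, tiny_models, rng):
        x, y = rng.random((2, 1, 1, 64, 64))
        bw = BaselineWeights(lambda_cyc=7.0, lambda_idt=3.0)
        total, bd = baseline_loss(Tensor(x), Tensor(y), tiny_models, bw)
        expected = bd["adv_xy"] + bd["adv_yx"] + 7.0 * bd["cycle"] + 3.0 * bd["identity"]
        assert float(total.data) == pytest.approx(expected, abs=1e-6)


class TestCyclicPerceptualLoss:
    def test_identity_generators_zero(self, rng):
        x, y = rng.random((2, 32, 32))
        ext = build_extractor("random", seed=0, layers=(1, 2))
        g = _IdentityGen()
        assert cyclic_perceptual_loss(x, y, g, g, ext) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_under_domain_swap(self, tiny_models, rng):
        x, y = rng.random((2, 64, 64))
        ext = build_extractor("random", seed=0, layers=(2, 5))
        a = cyclic_perceptual_loss(x, y, tiny_models.g_xy, tiny_models.g_yx, ext)
        b = cyclic_perceptual_loss(y, x, tiny_models.g_yx, tiny_models.g_xy, ext)
        assert a == pytest.approx(b, abs=1e-9)

    def test_composition_oracle_with_tiny_extractor(self, rng):
        """Matches a hand-composed extract/subtract/square/sum pipeline."""
        x, y = rng.random((2, 32, 32))

        class Blur:
            def __call__(self, t):
                import octaclear.nn as nn

                t = nn.as_tensor(t)
                if t.data.ndim == 2:
                    t = t.reshape((1, 1) + t.data.shape)
                return [t * 2.0, nn.maxpool2(t)]

        class Shift:
            def __call__(self, x):
                from octaclear.nn.tensor import as_tensor

                return as_tensor(x) + 0.05

        g = Shift()
        val = cyclic_perceptual_loss(x, y, g, g, Blur())
        # both generators add 0.05, so the cycle adds 0.1 to every pixel
        rx_err = 0.1
        n = 32 * 32
        expected = 2 * ((2 * rx_err) ** 2 * n + rx_err**2 * (n // 4))
        assert val == pytest.approx(expected, rel=1e-6)

    def test_linear_extractor_reduces_to_image_space_cycle(self, tiny_models, rng):
        x, y = rng.random((2, 64, 64))
        ext = LinearFeatureExtractor()
        val = cyclic_perceptual_loss(x, y, tiny_models.g_xy, tiny_models.g_yx, ext)
        rx = tiny_models.g_yx(tiny_models.g_xy(Tensor(x[None, None]))).data[0, 0]
        ry = tiny_models.g_xy(tiny_models.g_yx(Tensor(y[None, None]))).data[0, 0]
        expected = ((x - rx) ** 2).sum() + ((y - ry) ** 2).sum()
        assert val == pytest.approx(expected, rel=1e-9)


class TestStructureLoss:
    def test_identical_images_zero(self, rng):
        x = rng.random((32, 32))
        assert structure_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        x = rng.random((32, 32))
        gx = 0.7 * x + 0.1
        assert structure_loss(x, gx) == pytest.approx(0.0, abs=1e-6)

    def test_negated_high_variance_image_approaches_two(self, rng):
        x = rng.random((32, 32))  # per-window variance >> c
        w = EnhanceWeights()
        val = structure_loss(x, 1.0 - x, w)
        # each window term is (-var + c) / (var + c); compute the oracle
        terms = []
        for i in range(4):
            for j in range(4):
                tile = x[8 * i : 8 * i + 8, 8 * j : 8 * j + 8]
                var = tile.var()
                terms.append((-var + w.c) / (var + w.c))
        assert val == pytest.approx(1 - np.mean(terms), abs=1e-9)
        assert val > 1.9

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = rng.random((2, 16, 16))
            assert 0.0 <= structure_loss(a, b) <= 2.0

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            structure_loss(rng.random((4, 4)), rng.random((4, 4)))


class TestPSGANLoss:
    def test_zero_extra_weights_reduce_to_baseline(self, tiny_models, rng):
        x, y = rng.random((2, 1, 1, 64, 64))
        cfg = PSGANConfig.tiny(weights=EnhanceWeights(xi=0.0, rho1=0.0, rho2=0.0))
        ext = build_extractor("random", seed=1)
        total, _ = psgan_loss(Tensor(x), Tensor(y), tiny_models, ext, cfg)
        base, _ = baseline_loss(Tensor(x), Tensor(y), tiny_models, cfg.baseline)
        assert float(total.data) == pytest.approx(float(base.data), abs=1e-12)

    def test_identity_generators_kill_structural_terms(self, tiny_models, rng):
        # fresh (zero-init) generators are identities: L_p = L_s = 0
        x, y = rng.random((2, 1, 1, 64, 64))
        cfg = PSGANConfig.tiny(seed=3)
        ext = build_extractor("random", seed=1)
        _, bd = psgan_loss(Tensor(x), Tensor(y), tiny_models, ext, cfg)
        assert bd["perceptual"] == pytest.approx(0.0, abs=1e-12)
        assert bd["structure_x"] == pytest.approx(0.0, abs=1e-10)
        assert bd["structure_y"] == pytest.approx(0.0, abs=1e-10)

    def test_weighted_sum_oracle(self, rng):
        # train a couple of steps so generators are no longer identities
        xs = [rng.random((32, 32)) for _ in range(2)]
        ys = [rng.random((32, 32)) for _ in range(2)]
        cfg = PSGANConfig.tiny(image_size=32, epochs_constant=1, epochs_decay=0)
        models, _ = train_psgan(xs, ys, cfg)
        ext = build_extractor("random", seed=cfg.seed + 7)
        x, y = rng.random((2, 1, 1, 32, 32))
        total, bd = psgan_loss(Tensor(x), Tensor(y), models, ext, cfg)
        base, _ = baseline_loss(Tensor(x), Tensor(y), models, cfg.baseline)
        w = cfg.weights
        expected = (
            float(base.data)
            + w.xi * bd["perceptual"]
            + w.rho1 * bd["structure_x"]
            + w.rho2 * bd["structure_y"]
        )
        assert float(total.data) == pytest.approx(expected, abs=1e-6)


class TestTraining:
    def test_smoke_history_finite_and_reproducible(self, pools):
        xs, ys = pools
        cfg = PSGANConfig.tiny(epochs_constant=1, epochs_decay=0, seed=11)
        _, h1 = train_psgan(xs[:2], ys[:2], cfg)
        assert len(h1) == 1
        numeric = h1.drop(columns=["epoch"])
        assert np.isfinite(numeric.to_numpy()).all()
        _, h2 = train_psgan(xs[:2], ys[:2], cfg)
        assert np.allclose(h1.to_numpy(), h2.to_numpy(), atol=1e-12)

    def test_empty_domain_rejected(self, pools):
        with pytest.raises(ValueError, match="domain"):
            train_psgan([], pools[1], PSGANConfig.tiny())


class TestEnhance:
    def test_range_determinism_and_identity_profile(self, tiny_models, rng):
        img = rng.random((64, 64))
        out1 = enhance(tiny_models.g_xy, img)
        out2 = enhance(tiny_models.g_xy, img)
        assert np.array_equal(out1, out2)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        # untrained identity-initialized generator: output ~ input
        assert np.abs(out1 - img).max() <= 0.1

    def test_odd_size_pad_and_crop(self, tiny_models, rng):
        img = rng.random((33, 47))
        assert enhance(tiny_models.g_xy, img).shape == (33, 47)


def test_save_load_round_trip(pools, tmp_path, rng):
    xs, ys = pools
    cfg = PSGANConfig.tiny(epochs_constant=1, epochs_decay=0)
    models, _ = train_psgan(xs[:2], ys[:2], cfg)
    save_psgan(models, cfg, tmp_path / "g.npz")
    loaded, _ = load_psgan(tmp_path / "g.npz")
    img = rng.random((64, 64))
    np.testing.assert_array_equal(enhance(models.g_xy, img), enhance(loaded.g_xy, img))
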