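"""Network computation-graph contracts and hand-written gradients."""

import numpy as np
import pytest

from spinerecon import nn
from spinerecon.imaging import PatchPair
from spinerecon.network import (Discriminator, DiscriminatorConfig,
                                FusionStem, Generator, GeneratorConfig,
                                lift_to_3d, load_checkpoint, nonlocal_block,
                                save_checkpoint)
from _oracles import dense_attention


def finite_diff_check(module, x, loss_rng, n_per_param=4, eps=1e-6, tol=1e-6):
    """Compare analytic parameter/input gradients with central differences."""
    for m in module.modules():
        if isinstance(m, nn.BatchNorm):
            m.momentum = 0.0  # keep forward stationary between FD evaluations
    module.zero_grad()
    y = module.forward(x)
    dy = loss_rng.standard_normal(y.shape)
    dx = module.backward(dy)

    def loss():
        return float(np.sum(module.forward(x) * dy))

    def probe(arr, grad):
        flat = arr.ravel()
        idxs = loss_rng.choice(flat.size, size=min(n_per_param, flat.size),
                               replace=False)
        for i in idxs:
            old = flat[i]
            flat[i] = old + eps
            vp = loss()
            flat[i] = old - eps
            vm = loss()
            flat[i] = old
            num = (vp - vm) / (2 * eps)
            assert abs(num - grad.ravel()[i]) <= tol * max(1.0, abs(num))

    for _, p in module.parameters():
        probe(p.value, p.grad)
    probe(x, dx)


@pytest.mark.parametrize("name", ["conv3d_s1", "conv3d_s2", "conv2d",
                                  "conv1x1", "batchnorm", "sigmoid",
                                  "upsample", "nonlocal", "resblock"])
def test_layer_gradients_match_finite_differences(name, rng):
    with nn.default_dtype(np.float64):
        factory = {
            "conv3d_s1": lambda: (nn.Conv3d(3, 4, 3, rng=rng),
                                  rng.standard_normal((2, 3, 6, 6, 6))),
            "conv3d_s2": lambda: (nn.Conv3d(3, 4, 3, stride=2, rng=rng),
                                  rng.standard_normal((2, 3, 8, 8, 8))),
            "conv2d": lambda: (nn.Conv2d(2, 3, 3, rng=rng),
                               rng.standard_normal((2, 2, 7, 7))),
            "conv1x1": lambda: (nn.Conv2d(2, 3, 1, rng=rng),
                                rng.standard_normal((2, 2, 5, 5))),
            "batchnorm": lambda: (nn.BatchNorm(3),
                                  rng.standard_normal((4, 3, 5, 5))),
            "sigmoid": lambda: (nn.Sigmoid(),
                                rng.standard_normal((2, 3, 4, 4))),
            "upsample": lambda: (nn.Upsample3dNearest(),
                                 rng.standard_normal((2, 2, 4, 4, 4))),
            "nonlocal": lambda: (nn.NonLocal2d(4, rng=rng),
                                 rng.standard_normal((2, 4, 5, 5))),
            "resblock": lambda: (nn.ResBlock3d(2, 3, rng),
                                 rng.standard_normal((2, 2, 6, 6, 6))),
        }[name]
        module, x = factory()
    finite_diff_check(module, x, rng)


class TestNonLocal:
    def test_zero_projection_gives_residual_identity(self, rng):
        with nn.default_dtype(np.float64):
            block = nn.NonLocal2d(4, rng=rng)
        block.proj.weight.value[...] = 0.0
        block.proj.bias.value[...] = 0.0
        x = rng.standard_normal((4, 6, 6))
        np.testing.assert_array_equal(nonlocal_block(x, block), x)

    def test_single_position_softmax_is_one(self, rng):
        with nn.default_dtype(np.float64):
            block = nn.NonLocal2d(4, rng=rng)
        x = rng.standard_normal((4, 1, 1))
        # softmax over one key position = 1, so output = x + proj(sigma(x))
        sig = (block.sigma.weight.value[:, :, 0, 0] @ x[:, 0, 0]
               + block.sigma.bias.value)
        expected = x[:, 0, 0] + (block.proj.weight.value[:, :, 0, 0] @ sig
                                 + block.proj.bias.value)
        np.testing.assert_allclose(nonlocal_block(x, block)[:, 0, 0],
                                   expected, rtol=1e-12)

    def test_matches_dense_attention_oracle(self, rng):
        with nn.default_dtype(np.float64):
            block = nn.NonLocal2d(6, rng=rng)
        x = rng.standard_normal((6, 4, 4))
        expected = dense_attention(
            x,
            block.theta.weight.value[:, :, 0, 0], block.theta.bias.value,
            block.phi.weight.value[:, :, 0, 0], block.phi.bias.value,
            block.sigma.weight.value[:, :, 0, 0], block.sigma.bias.value,
            block.proj.weight.value[:, :, 0, 0], block.proj.bias.value)
        np.testing.assert_allclose(nonlocal_block(x, block), expected,
                                   atol=1e-10)


class TestLift:
    def test_coronal_slices_replicate_source(self, rng):
        cor = rng.standard_normal((1, 3, 5, 5))
        sag = rng.standard_normal((1, 2, 5, 5))
        vol = lift_to_3d(cor, sag)
        assert vol.shape == (1, 5, 5, 5, 5)
        for j in range(5):
            np.testing.assert_array_equal(vol[:, :3, :, j, :], cor)

    def test_sagittal_slices_replicate_source(self, rng):
        cor = rng.standard_normal((1, 2, 4, 4))
        sag = rng.standard_normal((1, 2, 4, 4))
        vol = lift_to_3d(cor, sag)
        for i in range(4):
            np.testing.assert_array_equal(vol[:, 2:, i, :, :], sag)

    def test_duplication_count_equals_patch_size(self, rng):
        s = 8
        cor = rng.standard_normal((1, 1, s, s))
        vol = lift_to_3d(cor, cor)
        assert vol.shape[2:] == (s, s, s)  # each view duplicated s times

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            lift_to_3d(rng.standard_normal((1, 1, 4, 4)),
                       rng.standard_normal((1, 1, 5, 5)))


class TestFusionStem:
    def test_output_shape_and_finite_on_zero_input(self, rng):
        config = GeneratorConfig(patch_size=16, base_channels=4, depth=2,
                                 fusion_channels=3)
        stem = FusionStem(config, rng)
        out = stem.forward(np.zeros((1, 16, 16)), np.zeros((1, 16, 16)))
        assert out.shape == (1, 3, 16, 16)
        assert np.isfinite(out).all()

    def test_swapping_channels_changes_output(self, rng):
        config = GeneratorConfig(patch_size=8, base_channels=4, depth=2,
                                 fusion_channels=3)
        stem = FusionStem(config, rng)
        stem.set_training(False)
        a = rng.random((1, 8, 8))
        b = rng.random((1, 8, 8))
        assert not np.allclose(stem.forward(a, b), stem.forward(b, a))


@pytest.fixture(scope="module")
def gen():
    config = GeneratorConfig(patch_size=16, base_channels=4, depth=3,
                             fusion_channels=2)
    return Generator(config, np.random.default_rng(0)), config


class TestGenerator:
    def test_output_cubic_and_bounded(self, gen, rng):
        g, config = gen
        g.set_training(False)
        x = [rng.random((2, 16, 16)).astype(np.float32) for _ in range(4)]
        out = g.forward(*x)
        assert out.shape == (2, 16, 16, 16)
        assert (out > 0).all() and (out < 1).all()  # sigmoid output

    def test_eval_mode_deterministic(self, gen, rng):
        g, _ = gen
        g.set_training(False)
        x = [rng.random((1, 16, 16)).astype(np.float32) for _ in range(4)]
        np.testing.assert_array_equal(g.forward(*x), g.forward(*x))

    def test_end_to_end_gradients(self, rng):
        # composite check; a few ReLU kinks can spoil single finite
        # differences, so require the bulk of probes to agree tightly
        with nn.default_dtype(np.float64):
            config = GeneratorConfig(patch_size=8, base_channels=2, depth=2,
                                     fusion_channels=2)
            g = Generator(config, np.random.default_rng(3))
        for m in g.modules():
            if isinstance(m, nn.BatchNorm):
                m.momentum = 0.0
        x = [rng.random((2, 8, 8)) for _ in range(4)]
        tgt = (rng.random((2, 8, 8, 8)) > 0.7).astype(float)
        g.zero_grad()
        out = g.forward(*x)
        g.backward(2 * (out - tgt))

        def loss():
            return float(np.sum((g.forward(*x) - tgt) ** 2))

        errs = []
        for _, p in g.parameters():
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + 1e-6
                vp = loss()
                flat[i] = old - 1e-6
                vm = loss()
                flat[i] = old
                num = (vp - vm) / 2e-6
                errs.append(abs(num - p.grad.ravel()[i]) / max(1.0, abs(num)))
        errs = np.array(errs)
        assert np.median(errs) < 1e-6
        assert (errs < 1e-3).mean() > 0.9


class TestDiscriminator:
    def test_score_map_strictly_smaller_and_deterministic(self, rng):
        config = DiscriminatorConfig(patch_size=32, base_channels=2, n_layers=4)
        d = Discriminator(config, np.random.default_rng(1))
        d.set_training(False)
        v = rng.random((1, 32, 32, 32)).astype(np.float32)
        s = d.forward(v)
        assert all(a < b for a, b in zip(s.shape[1:], v.shape[1:]))
        np.testing.assert_array_equal(s, d.forward(v))

    def test_translation_covariance_on_interior(self, rng):
        config = DiscriminatorConfig(patch_size=64, base_channels=2, n_layers=3)
        d = Discriminator(config, np.random.default_rng(2))
        d.set_training(False)
        stride = 2 ** 3
        v = np.zeros((1, 64, 64, 64), dtype=np.float64)
        v[0, 16:32, 24:40, 24:40] = rng.random((16, 16, 16))
        shifted = np.roll(v, stride, axis=1)
        s = d.forward(v)[0]
        s_sh = d.forward(shifted)[0]
        np.testing.assert_allclose(s_sh[3:6, 2:6, 2:6], s[2:5, 2:6, 2:6],
                                   atol=1e-8)


class TestCheckpoints:
    def test_round_trip_identical_outputs(self, tmp_path, rng):
        config = GeneratorConfig(patch_size=16, base_channels=4, depth=2,
                                 fusion_channels=2)
        g = Generator(config, np.random.default_rng(5))
        g.set_training(False)
        x = [rng.random((1, 16, 16)).astype(np.float32) for _ in range(4)]
        before = g.forward(*x)
        path = tmp_path / "gen.npz"
        save_checkpoint(path, g, config)
        g2, config2 = load_checkpoint(path, Generator, GeneratorConfig)
        g2.set_training(False)
        assert config2 == config
        np.testing.assert_array_equal(before, g2.forward(*x))

    def test_shape_mismatch_rejected(self, tmp_path):
        config = GeneratorConfig(patch_size=16, base_channels=4, depth=2,
                                 fusion_channels=2)
        g = Generator(config, np.random.default_rng(5))
        state = g.state_dict()
        key = next(iter(state))
        state[key] = np.zeros((1, 1))
        with pytest.raises(ValueError, match="shape mismatch"):
            g.load_state_dict(state)


def test_config_invariants():
    with pytest.raises(ValueError):
        GeneratorConfig(patch_size=30, depth=3)  # not divisible by 2**(d-1)
    with pytest.raises(ValueError):
        GeneratorConfig(depth=1)
    assert GeneratorConfig().patch_size == 120


def test_pair_validation_catches_shape_and_range(rng):
    ok = dict(coronal_patch=np.zeros((8, 8)) + 0.5,
              sagittal_patch=np.zeros((8, 8)) + 0.5,
              coronal_centroid_mask=np.eye(8, dtype=bool),
              sagittal_centroid_mask=np.eye(8, dtype=bool),
              vertebra_label="L1", subject_id="s")
    PatchPair(**ok)
    bad = dict(ok, coronal_patch=np.zeros((8, 8)) + 1.5)
    with pytest.raises(ValueError):
        PatchPair(**bad)
    bad = dict(ok, coronal_centroid_mask=np.zeros((8, 8), dtype=bool))
    with pytest.raises(ValueError):
        PatchPair(**bad)
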