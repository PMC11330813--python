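"""Backbone assembly: residual identity, shape contracts, parameter-count
tally, ablation lattice, determinism."""

import numpy as np
import pytest

from maresnet.backbone import (ConfigurationError, ModelConfig, ResidualBlock,
                               ShapeError, build_model, count_parameters,
                               model_name, parameter_report)
from maresnet.nn import Conv2d

from conftest import cast_model_to
from oracles import direct_conv2d, param_tally, relu, batchnorm_train


def unet_config(**kw):
    kw.setdefault("use_residual", False)
    kw.setdefault("use_sfem", False)
    kw.setdefault("use_mcem", False)
    kw.setdefault("use_ag", False)
    return ModelConfig(**kw)


class TestResidualBlock:
    def test_zeroed_f_path_is_identity(self, rng):
        """With all conv weights zero the residual limit y = f(x) + x = x."""
        block = ResidualBlock(4, 4, rng=rng, dtype=np.float64)
        for layer in block.f.layers:
            if isinstance(layer, Conv2d):
                layer.w.value[...] = 0.0
        x = rng.standard_normal((2, 5, 5, 4))
        np.testing.assert_array_equal(block.forward(x), x)

    def test_shape_preserved(self, rng):
        block = ResidualBlock(16, 16, rng=rng)
        x = rng.standard_normal((1, 32, 32, 16)).astype(np.float32)
        assert block.forward(x).shape == (1, 32, 32, 16)

    def test_matches_composed_direct_convolutions(self, rng):
        """f(x) + x recomputed tap-by-tap on a 4x4 grid."""
        block = ResidualBlock(2, 2, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 4, 4, 2))
        got = block.forward(x, train=True)
        c1, b1, _, c2, b2, _ = block.f.layers
        h = relu(batchnorm_train(
            direct_conv2d(x[0], c1.w.value, c1.b.value)[None],
            b1.gamma.value, b1.beta.value))
        h = relu(batchnorm_train(
            direct_conv2d(h[0], c2.w.value, c2.b.value)[None],
            b2.gamma.value, b2.beta.value))
        np.testing.assert_allclose(got, h + x, atol=1e-10)

    def test_projection_shortcut_when_channels_change(self, rng):
        block = ResidualBlock(2, 6, rng=rng)
        assert block.shortcut is not None
        x = rng.standard_normal((1, 4, 4, 2)).astype(np.float32)
        assert block.forward(x).shape == (1, 4, 4, 6)

    def test_nonpositive_out_channels_rejected(self, rng):
        with pytest.raises((ConfigurationError, ValueError)):
            ResidualBlock(4, 0, rng=rng)


class TestEncoderDecoder:
    def test_stage_geometry_256(self):
        model = build_model(unet_config())
        x = np.zeros((1, 256, 256, 1), dtype=np.float32)
        state = model.encode(x)
        assert [f.shape[3] for f in state.stage_features] == [16, 32, 64, 128]
        assert [f.shape[1] for f in state.stage_features] == [256, 128, 64, 32]
        assert state.bottleneck.shape == (1, 16, 16, 256)

    def test_bottleneck_geometry_64(self):
        model = build_model(unet_config())
        state = model.encode(np.zeros((1, 64, 64, 1), dtype=np.float32))
        assert state.bottleneck.shape == (1, 4, 4, 256)

    def test_indivisible_size_names_dimension(self):
        model = build_model(unet_config())
        with pytest.raises(ShapeError, match="height 250"):
            model.encode(np.zeros((1, 250, 250, 1), dtype=np.float32))
        with pytest.raises(ShapeError, match="width 250"):
            model.encode(np.zeros((1, 256, 250, 1), dtype=np.float32))

    def test_skip_mismatch_raises(self):
        model = build_model(unet_config())
        state = model.encode(np.zeros((1, 64, 64, 1), dtype=np.float32))
        bad = [np.zeros_like(s)[:, ::2] for s in state.stage_features]
        with pytest.raises(ShapeError, match="spatial size"):
            model.decode(state, bad)

    @pytest.mark.parametrize("size", [64, 256])
    @pytest.mark.parametrize("full", [False, True])
    def test_end_to_end_shape_and_range(self, size, full):
        cfg = ModelConfig(seed=1) if full else unet_config(seed=1)
        model = build_model(cfg)
        x = np.random.default_rng(0).random((1, size, size, 1),
                                            dtype=np.float32)
        prob = model.forward(x, train=False)
        assert prob.shape == (1, size, size, 1)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_ag_off_passes_skip_unmodified(self, rng):
        """Without gates the decoder consumes the raw skip: outputs of two
        builds differing only in use_ag disagree, but the config reports no
        gate layers and the skip tensor is concatenated as-is."""
        model = build_model(unet_config(use_residual=True))
        assert model.gates == []
        # decode with hand-supplied skips: zeroing one skip must change the
        # output only through the concatenation path
        x = rng.random((1, 64, 64, 1)).astype(np.float32)
        state = model.encode(x, train=False)
        out1 = model.decode(state, state.stage_features, train=False)
        zeroed = [np.zeros_like(s) for s in state.stage_features]
        out2 = model.decode(state, zeroed, train=False)
        assert not np.allclose(out1, out2)


class TestParameterCounts:
    def test_single_conv_count(self, rng):
        conv = Conv2d(1, 16, k=3, rng=rng)
        assert conv.w.value.size + conv.b.value.size == 160

    def test_unet_matches_layer_tally(self):
        model = build_model(unet_config())
        assert count_parameters(model) == param_tally(16, 4, 1)

    def test_full_model_matches_layer_tally(self):
        model = build_model(ModelConfig())
        want = param_tally(16, 4, 1, residual=True, sfem=True, mcem=True,
                           ag=True)
        assert count_parameters(model) == want

    def test_ablation_lattice_monotone(self):
        base = count_parameters(build_model(unet_config()))
        for flag in ("use_residual", "use_sfem", "use_mcem", "use_ag"):
            n = count_parameters(build_model(unet_config(**{flag: True})))
            assert n > base, flag

    def test_report_units(self):
        rep = parameter_report(unet_config())
        assert rep["model"] == "U-Net"
        assert rep["millions"] == round(rep["parameters"] / 1e6, 2)


class TestDeterminism:
    def test_same_seed_same_weights_and_output(self):
        cfg = ModelConfig(base_width=4, depth=2, seed=7)
        m1, m2 = build_model(cfg), build_model(cfg)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)
        x = np.random.default_rng(3).random((1, 16, 16, 1), dtype=np.float32)
        np.testing.assert_array_equal(m1.forward(x, train=False),
                                      m2.forward(x, train=False))

    def test_different_seed_different_weights(self):
        m1 = build_model(ModelConfig(base_width=4, depth=2, seed=1))
        m2 = build_model(ModelConfig(base_width=4, depth=2, seed=2))
        assert any((p1.value != p2.value).any()
                   for p1, p2 in zip(m1.parameters(), m2.parameters()))


class TestModelName:
    @pytest.mark.parametrize("flags,name", [
        (dict(use_residual=True, use_ag=True, use_sfem=True, use_mcem=True),
         "MARes-Net"),
        (dict(use_residual=False, use_ag=False, use_sfem=False,
              use_mcem=False), "U-Net"),
        (dict(use_residual=True, use_ag=False, use_sfem=False,
              use_mcem=False), "ResU"),
        (dict(use_residual=True, use_ag=True, use_sfem=True, use_mcem=False),
         "ResU + AG + SFEM"),
        (dict(use_residual=False, use_ag=True, use_sfem=True, use_mcem=True),
         "U-Net + AG + SFEM + MCEM"),
    ])
    def test_names(self, flags, name):
        assert model_name(ModelConfig(**flags)) == name


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        ModelConfig(base_width=2).validate()
    with pytest.raises(ConfigurationError):
        ModelConfig(depth=1).validate()
    with pytest.raises(ConfigurationError):
        ModelConfig(sfem_attention="transformer").validate()


def test_full_model_gradient_check(rng):
    """Finite-difference check of the assembled network (all modules on)."""
    from maresnet.metrics import dice_loss, dice_loss_grad
    from maresnet.nn import zero_grads

    model = cast_model_to(build_model(ModelConfig(base_width=4, depth=2,
                                                  seed=3, dtype="float64")),
                          np.float64)
    x = rng.standard_normal((1, 8, 8, 1))
    t = (rng.random((1, 8, 8, 1)) > 0.5).astype(float)
    params = model.parameters()
    zero_grads(params)
    prob = model.forward(x, train=True)
    model.backward(dice_loss_grad(prob, t))
    eps = 1e-6
    checked = 0
    for p in params[:: max(1, len(params) // 12)]:
        flat = p.value.ravel()
        idx = int(rng.integers(0, flat.size))
        orig = flat[idx]
        flat[idx] = orig + eps
        lp = dice_loss(model.forward(x, train=True), t)
        flat[idx] = orig - eps
        lm = dice_loss(model.forward(x, train=True), t)
        flat[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - p.grad.ravel()[idx]) < 1e-6 * max(1.0, abs(num))
        checked += 1
    assert checked >= 10
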