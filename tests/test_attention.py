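"""Attention primitives against hand arithmetic: SE closed form, CAM/SAM
oracles, CBAM composition, attention-gate limits."""

import numpy as np
import pytest

from maresnet.attention import (AttentionGate, CBAM, ChannelAttention, SEBlock,
                                SpatialAttention, make_attention)

from oracles import direct_conv2d, se_gains, sigmoid


class TestSEBlock:
    def test_forced_unit_gains_identity(self, rng):
        se = SEBlock(4, reduction=16, rng=rng, dtype=np.float64)
        se.w1.value[...] = 0; se.b1.value[...] = 0
        se.w2.value[...] = 0
        se.b2.value[...] = 1e4  # sigmoid(1e4) == 1 to machine precision
        x = rng.standard_normal((2, 5, 5, 4))
        np.testing.assert_allclose(se.forward(x), x, atol=1e-12)

    def test_constant_input_closed_form(self, rng):
        se = SEBlock(3, reduction=1, rng=rng, dtype=np.float64)
        x = np.full((1, 4, 4, 3), 0.0)
        x[..., 0], x[..., 1], x[..., 2] = 0.5, -1.0, 2.0
        got = se.forward(x)
        gains = se_gains(np.array([0.5, -1.0, 2.0]), se.w1.value, se.b1.value,
                         se.w2.value, se.b2.value)
        np.testing.assert_allclose(got[0, 0, 0], np.array([0.5, -1.0, 2.0]) * gains,
                                   atol=1e-12)

    def test_hidden_width_and_shape(self, rng):
        se = SEBlock(64, reduction=16, rng=rng)
        assert se.hidden == 4
        x = rng.standard_normal((1, 32, 32, 64)).astype(np.float32)
        assert se.forward(x).shape == (1, 32, 32, 64)

    def test_zero_second_layer_gives_half_gains(self, rng):
        """reduction = channels and zero output weights: gain sigmoid(0)=0.5."""
        se = SEBlock(8, reduction=8, rng=rng, dtype=np.float64)
        se.w2.value[...] = 0; se.b2.value[...] = 0
        x = rng.standard_normal((1, 3, 3, 8))
        np.testing.assert_allclose(se.forward(x), 0.5 * x, atol=1e-12)


class TestChannelAttention:
    def test_hand_set_mlp_oracle(self, rng):
        """4-channel toy map; weights recomputed by manual matrix arithmetic."""
        cam = ChannelAttention(4, reduction=1, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 3, 3, 4))
        got = cam.forward(x)
        avg = x[0].mean(axis=(0, 1))
        mx = x[0].max(axis=(0, 1))

        def mlp(v):
            return np.maximum(v @ cam.w1.value + cam.b1.value, 0) \
                @ cam.w2.value + cam.b2.value

        np.testing.assert_allclose(got[0], sigmoid(mlp(avg) + mlp(mx)),
                                   atol=1e-12)

    def test_spatially_constant_input_pooling_coincidence(self, rng):
        cam = ChannelAttention(3, reduction=1, rng=rng, dtype=np.float64)
        v = np.array([1.0, -0.5, 2.0])
        x = np.broadcast_to(v, (1, 4, 4, 3)).copy()
        got = cam.forward(x)

        def mlp(u):
            return np.maximum(u @ cam.w1.value + cam.b1.value, 0) \
                @ cam.w2.value + cam.b2.value

        np.testing.assert_allclose(got[0], sigmoid(2 * mlp(v)), atol=1e-12)

    def test_weights_in_open_unit_interval(self, rng):
        cam = ChannelAttention(8, rng=rng, dtype=np.float64)
        w = cam.forward(rng.standard_normal((3, 6, 6, 8)))
        assert (w > 0).all() and (w < 1).all()

    def test_invariant_to_spatial_permutation(self, rng):
        cam = ChannelAttention(5, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 4, 4, 5))
        perm = rng.permutation(16)
        xp = x.reshape(1, 16, 5)[:, perm].reshape(1, 4, 4, 5)
        np.testing.assert_allclose(cam.forward(x), cam.forward(xp), atol=1e-12)

    def test_printed_form_sums_after_sigmoid(self, rng):
        cam = ChannelAttention(3, reduction=1, printed_form=True, rng=rng,
                               dtype=np.float64)
        v = np.array([0.3, -1.0, 0.7])
        x = np.broadcast_to(v, (1, 2, 2, 3)).copy()

        def mlp(u):
            return np.maximum(u @ cam.w1.value + cam.b1.value, 0) \
                @ cam.w2.value + cam.b2.value

        np.testing.assert_allclose(cam.forward(x)[0], 2 * sigmoid(mlp(v)),
                                   atol=1e-12)


class TestSpatialAttention:
    def test_output_single_channel_any_width(self, rng):
        for c in (1, 3, 16):
            sam = SpatialAttention(rng=rng, dtype=np.float64)
            out = sam.forward(rng.standard_normal((2, 8, 8, c)))
            assert out.shape == (2, 8, 8, 1)

    def test_direct_convolution_oracle(self, rng):
        """5x5 toy grid: sigma(conv7x7([mean; max])) recomputed tap-by-tap."""
        sam = SpatialAttention(rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 5, 5, 3))
        got = sam.forward(x)
        stacked = np.concatenate([x[0].mean(axis=2, keepdims=True),
                                  x[0].max(axis=2, keepdims=True)], axis=2)
        want = sigmoid(direct_conv2d(stacked, sam.conv.w.value,
                                     sam.conv.b.value))
        np.testing.assert_allclose(got[0], want, atol=1e-12)

    def test_channel_constant_input_duplicated_map(self, rng):
        sam = SpatialAttention(rng=rng, dtype=np.float64)
        base = rng.standard_normal((1, 6, 6, 1))
        x = np.repeat(base, 4, axis=3)
        got = sam.forward(x)
        dup = np.concatenate([base[0], base[0]], axis=2)
        want = sigmoid(direct_conv2d(dup, sam.conv.w.value, sam.conv.b.value))
        np.testing.assert_allclose(got[0], want, atol=1e-12)

    def test_equivariant_to_spatial_flip(self, rng):
        sam = SpatialAttention(rng=rng, dtype=np.float64)
        # flipping the input and flipping the kernel flips the output
        x = rng.standard_normal((1, 6, 6, 3))
        out = sam.forward(x)
        sam.conv.w.value = sam.conv.w.value[::-1, ::-1].copy()
        out_flip = sam.forward(x[:, ::-1, ::-1])
        np.testing.assert_allclose(out_flip, out[:, ::-1, ::-1], atol=1e-12)


class TestCBAM:
    def test_composition_of_oracles(self, rng):
        """4x4x2 toy input equals CAM gate then SAM gate applied manually."""
        cbam = CBAM(2, reduction=1, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 4, 4, 2))
        got = cbam.forward(x)
        sc = cbam.cam.forward(x)
        xp = x * sc[:, None, None, :]
        stacked = np.concatenate([xp[0].mean(axis=2, keepdims=True),
                                  xp[0].max(axis=2, keepdims=True)], axis=2)
        ss = sigmoid(direct_conv2d(stacked, cbam.sam.conv.w.value,
                                   cbam.sam.conv.b.value))
        np.testing.assert_allclose(got[0], xp[0] * ss, atol=1e-12)

    def test_gated_magnitude_never_exceeds_input(self, rng):
        cbam = CBAM(4, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 6, 6, 4))
        assert (np.abs(cbam.forward(x)) <= np.abs(x) + 1e-15).all()

    def test_shape_preserved(self, rng):
        cbam = CBAM(8, rng=rng)
        x = rng.standard_normal((1, 16, 16, 8)).astype(np.float32)
        assert cbam.forward(x).shape == x.shape


class TestAttentionGate:
    def _force_alpha(self, ag, logit):
        ag.psi.w.value[...] = 0.0
        ag.psi.b.value[...] = 0.0
        ag.bn_psi.gamma.value[...] = 0.0
        ag.bn_psi.beta.value[...] = logit

    def test_alpha_one_passes_skip(self, rng):
        ag = AttentionGate(4, 4, rng=rng, dtype=np.float64)
        self._force_alpha(ag, 1e4)  # sigmoid -> 1
        gate = rng.standard_normal((1, 5, 5, 4))
        skip = rng.standard_normal((1, 5, 5, 4))
        np.testing.assert_allclose(ag(gate, skip), skip, atol=1e-12)

    def test_alpha_zero_suppresses_everything(self, rng):
        ag = AttentionGate(4, 4, rng=rng, dtype=np.float64)
        self._force_alpha(ag, -1e4)  # sigmoid -> 0
        gate = rng.standard_normal((1, 5, 5, 4))
        skip = rng.standard_normal((1, 5, 5, 4))
        np.testing.assert_allclose(ag(gate, skip), 0.0, atol=1e-12)

    def test_toy_hand_computed_alpha(self, rng):
        """2x2 inputs, 1x1 convs with hand-set weights, BN forced affine-
        neutral: alpha recomputable with scalar arithmetic."""
        ag = AttentionGate(1, 1, rng=rng, dtype=np.float64)
        # neutralise batch-norms: gamma * xhat + beta with batch stats is
        # data-dependent, so instead drive them towards identity by setting
        # eval mode and unit running stats
        for bn in (ag.bn_theta, ag.bn_phi, ag.bn_psi):
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0 - 1e-5
        ag.theta.w.value[...] = 2.0; ag.theta.b.value[...] = 0.0
        ag.phi.w.value[...] = 3.0; ag.phi.b.value[...] = 0.0
        ag.psi.w.value[...] = 1.0; ag.psi.b.value[...] = -1.0
        gate = np.array([[0.5, -1.0], [0.0, 2.0]]).reshape(1, 2, 2, 1)
        skip = np.array([[1.0, 1.0], [2.0, -1.0]]).reshape(1, 2, 2, 1)
        got = ag(gate, skip, train=False)
        pre = np.maximum(3.0 * gate + 2.0 * skip, 0.0)
        alpha = sigmoid(pre - 1.0)
        np.testing.assert_allclose(got, skip * alpha, atol=1e-12)

    def test_spatial_mismatch_raises(self, rng):
        ag = AttentionGate(4, 4, rng=rng)
        with pytest.raises(ValueError, match="spatial size"):
            ag(np.zeros((1, 4, 4, 4)), np.zeros((1, 8, 8, 4)))


def test_make_attention_variants(rng):
    x = np.random.default_rng(0).standard_normal((1, 4, 4, 4))
    for variant in ("none", "cam", "sam", "cbam"):
        layer = make_attention(variant, 4, rng=rng, dtype=np.float64)
        out = layer.forward(x)
        assert out.shape == x.shape
        if variant == "none":
            np.testing.assert_array_equal(out, x)
    with pytest.raises(ValueError):
        make_attention("bogus", 4, rng=rng)
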