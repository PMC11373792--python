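"""Residual classifiers, attention blocks and deformable convolution."""

import numpy as np
import pytest
from scipy.signal import correlate

from hyperseed.nn import (
    CBAMBlock,
    Conv2d,
    DeformableConv2d,
    ModelConfig,
    SEBlock,
    build_model,
    build_modified_model,
    build_resnet,
    module_census,
    softmax,
)


def conv_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                stride: int = 1, pad: int = 1) -> np.ndarray:
    """Independent standard cross-correlation via scipy, channel by channel."""
    n, c, h, w = x.shape
    o = weight.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    outs = np.zeros((n, o, xp.shape[2] - weight.shape[2] + 1, xp.shape[3] - weight.shape[3] + 1))
    for ni in range(n):
        for oi in range(o):
            acc = np.zeros(outs.shape[2:])
            for ci in range(c):
                acc += correlate(xp[ni, ci], weight[oi, ci], mode="valid")
            outs[ni, oi] = acc + bias[oi]
    return outs[:, :, ::stride, ::stride]


# ---------------------------------------------------------------------------
# independent per-layer parameter-count formulas


def _basic_stage(cin, cout, depth, first_stride):
    total = 0
    for b in range(depth):
        ci = cin if b == 0 else cout
        total += 9 * ci * cout + 2 * cout          # conv1 + bn1
        total += 9 * cout * cout + 2 * cout        # conv2 + bn2
        if b == 0 and (first_stride != 1 or ci != cout):
            total += ci * cout + 2 * cout          # 1x1 downsample + bn
    return total


def _bottleneck_stage(cin, mid, depth, first_stride):
    total = 0
    cout = 4 * mid
    for b in range(depth):
        ci = cin if b == 0 else cout
        total += ci * mid + 2 * mid
        total += 9 * mid * mid + 2 * mid
        total += mid * cout + 2 * cout
        if b == 0:
            total += ci * cout + 2 * cout
    return total


def expected_param_count(family: str, num_classes: int = 7) -> int:
    stem = 3 * 64 * 49 + 2 * 64
    depths = {
        "resnet18": (2, 2, 2, 2),
        "resnet34": (3, 4, 6, 3),
        "resnet50": (3, 4, 6, 3),
        "resnet101": (3, 4, 23, 3),
    }[family]
    total = stem
    if family in ("resnet18", "resnet34"):
        cin = 64
        for si, (width, d) in enumerate(zip((64, 128, 256, 512), depths)):
            total += _basic_stage(cin, width, d, 1 if si == 0 else 2)
            cin = width
        total += 512 * num_classes + num_classes
    else:
        cin = 64
        for si, (mid, d) in enumerate(zip((64, 128, 256, 512), depths)):
            total += _bottleneck_stage(cin, mid, d, 1 if si == 0 else 2)
            cin = 4 * mid
        total += 2048 * num_classes + num_classes
    return total


class TestPlainResNets:
    @pytest.mark.parametrize("family", ["resnet18", "resnet34", "resnet50", "resnet101"])
    def test_parameter_count_matches_layer_formula(self, family):
        model = build_resnet(ModelConfig(family=family, num_classes=7))
        assert model.n_parameters() == expected_param_count(family)

    def test_softmax_output_normalized(self):
        model = build_resnet(ModelConfig(family="resnet18", num_classes=7, rng_seed=1))
        x = np.random.default_rng(0).standard_normal((2, 3, 224, 224)).astype(np.float32)
        model.train(False)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 7)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_stage_spatial_sizes_for_224_input(self):
        """Stride bookkeeping: 224 -> 56 (stem+pool) -> 56, 28, 14, 7."""
        model = build_resnet(ModelConfig(family="resnet18", num_classes=7))
        model.train(False)
        x = np.zeros((1, 3, 224, 224), dtype=np.float32)
        out = model.stem_pool(model.stem_relu(model.stem_bn(model.stem_conv(x))))
        sizes = [out.shape[2]]
        for stage in model.stages:
            out = stage(out)
            sizes.append(out.shape[2])
        assert sizes == [56, 56, 28, 14, 7]

    def test_modified_family_rejected_by_plain_builder(self):
        with pytest.raises(ValueError):
            build_resnet(ModelConfig(family="se_resnet34"))


class TestSEBlock:
    def test_constant_channel_squeeze_is_value(self):
        se = SEBlock(3, reduction=1)
        x = np.zeros((2, 3, 4, 4), dtype=np.float32)
        x[:, 1] = 2.5
        np.testing.assert_allclose(se.squeeze(x)[:, 1], 2.5)

    def test_pinned_weights_scale_channels_exactly(self):
        """With the excitation output fixed, the block is elementwise
        channel scaling."""
        se = SEBlock(4, reduction=2, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 4, 5, 5)).astype(np.float32)
        w = se.excite(se.squeeze(x))
        out = se.forward(x)
        np.testing.assert_allclose(out, x * w[:, :, None, None], atol=1e-6)

    def test_weights_bounded_by_sigmoid(self):
        se = SEBlock(8, reduction=4, rng=np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((3, 8, 6, 6)).astype(np.float32)
        out = se.forward(x)
        assert (np.abs(out) <= np.abs(x) + 1e-6).all()
        assert out.shape == x.shape


class TestCBAMBlock:
    def test_channel_weights_depend_only_on_pooled_descriptors(self):
        """The channel stage sees the features only through their global
        average and max, so spatially permuting the input leaves the
        channel weights unchanged."""
        cbam = CBAMBlock(4, reduction=2, kernel_size=3, rng=np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 4, 5, 5)).astype(np.float32)
        perm = rng.permutation(25)
        x_perm = x.reshape(2, 4, 25)[:, :, perm].reshape(2, 4, 5, 5)
        np.testing.assert_allclose(
            cbam.channel_weights(x), cbam.channel_weights(x_perm), atol=1e-6
        )

    def test_spatial_weights_match_hand_arithmetic(self):
        """2x2 feature block, 1x1 spatial conv: sigmoid(w0*mean + w1*max + b)."""
        cbam = CBAMBlock(2, reduction=1, kernel_size=1, rng=np.random.default_rng(0))
        cbam.spatial_conv.weight.data = np.array([[[[0.5]], [[-1.0]]]], dtype=np.float32)
        cbam.spatial_conv.bias.data = np.array([0.25], dtype=np.float32)
        y = np.array([[[[1.0, 2.0], [3.0, 4.0]], [[2.0, 0.0], [1.0, 8.0]]]], dtype=np.float32)
        mean_map = y.mean(axis=1)
        max_map = y.max(axis=1)
        expected = 1 / (1 + np.exp(-(0.5 * mean_map - 1.0 * max_map + 0.25)))
        np.testing.assert_allclose(cbam.spatial_weights(y)[:, 0], expected, atol=1e-6)

    def test_channel_then_spatial_order(self):
        """The spatial map is computed on the channel-reweighted features,
        so scaling one channel changes the spatial weights — the signature
        of the sequential channel->spatial structure."""
        rng = np.random.default_rng(4)
        cbam = CBAMBlock(4, reduction=2, kernel_size=3, rng=rng)
        x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        out = cbam.forward(x)
        assert out.shape == x.shape
        wc = cbam.channel_weights(x)
        y = x * wc[:, :, None, None]
        ws_seq = cbam.spatial_weights(y)
        ws_raw = cbam.spatial_weights(x)
        assert not np.allclose(ws_seq, ws_raw)
        np.testing.assert_allclose(out, y * ws_seq, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CBAMBlock(4, kernel_size=4)


class TestDeformableConv:
    def test_zero_offset_equals_standard_convolution_100_inputs(self):
        """Degenerate equivalence against an independent scipy oracle."""
        rng = np.random.default_rng(11)
        for i in range(100):
            c, o = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            h = int(rng.integers(5, 9))
            d = DeformableConv2d(c, o, 3, stride=1, padding=1,
                                 rng=np.random.default_rng(100 + i))
            x = rng.standard_normal((1, c, h, h)).astype(np.float32)
            got = d.forward(x)
            want = conv_oracle(x.astype(np.float64), d.weight.data.astype(np.float64),
                               d.bias.data.astype(np.float64))
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_uniform_integer_offset_is_shifted_convolution(self):
        rng = np.random.default_rng(5)
        d = DeformableConv2d(2, 3, 3, stride=1, padding=0, rng=rng)
        # constant offset (0, 1): every tap samples one column to the right
        bias = np.zeros(18, dtype=np.float32)
        bias[1::2] = 1.0
        d.offset_conv.bias.data = bias
        x = rng.standard_normal((1, 2, 7, 7)).astype(np.float32)
        shifted = np.zeros_like(x)
        shifted[:, :, :, :-1] = x[:, :, :, 1:]
        got = d.forward(x)
        want = conv_oracle(shifted.astype(np.float64), d.weight.data.astype(np.float64),
                           d.bias.data.astype(np.float64), pad=0)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_half_pixel_offset_bilinear_average_1x1(self):
        d = DeformableConv2d(1, 1, 1, stride=1, padding=0, bias=False,
                             rng=np.random.default_rng(0))
        d.weight.data = np.ones_like(d.weight.data)
        x = np.arange(9, dtype=np.float32).reshape(1, 1, 3, 3)
        base = d.forward(x)
        np.testing.assert_allclose(base, x)  # zero offsets: identity with unit weight
        # column offset +0.5 at position (0, 0) only
        d.offset_conv.bias.data = np.zeros(2, dtype=np.float32)
        off = np.zeros((1, 2, 3, 3), dtype=np.float32)
        off[0, 1, 0, 0] = 0.5
        d.offset_conv.forward = lambda _: off  # pin the predicted offsets
        out = d.forward(x)
        assert out[0, 0, 0, 0] == pytest.approx((x[0, 0, 0, 0] + x[0, 0, 0, 1]) / 2)
        assert out[0, 0, 1, 1] == pytest.approx(x[0, 0, 1, 1])

    def test_offset_shape_mismatch_raises(self):
        d = DeformableConv2d(1, 1, 3, padding=1)
        d.offset_conv.forward = lambda _: np.zeros((1, 4, 3, 3), dtype=np.float32)
        with pytest.raises(ValueError, match="offset"):
            d.forward(np.zeros((1, 1, 3, 3), dtype=np.float32))


class TestModifiedModels:
    def test_se_resnet34_dcn_module_census(self):
        model = build_modified_model(ModelConfig(family="se_resnet34_dcn", num_classes=7))
        census = module_census(model)
        assert census["se"] == 2
        assert census["deformable_conv"] == 1
        assert census["linear"] == 1
        assert census["stages"] == 5  # stem + four residual stages

    def test_cbam_resnet34_census(self):
        census = module_census(build_modified_model(ModelConfig(family="cbam_resnet34")))
        assert census["cbam"] == 2 and census["se"] == 0

    @pytest.mark.parametrize("family", ["cbam_resnet34", "se_resnet34", "se_resnet34_dcn"])
    def test_modified_heads_emit_seven_logits(self, family):
        model = build_modified_model(ModelConfig(family=family, num_classes=7, rng_seed=2))
        model.train(False)
        x = np.random.default_rng(1).standard_normal((1, 3, 224, 224)).astype(np.float32)
        assert model.forward(x).shape == (1, 7)

    def test_se_pinned_to_identity_reproduces_plain_resnet34(self):
        """Ablation equivalence: neutralizing both SE blocks and copying the
        remaining weights into a plain ResNet34 gives identical outputs."""
        se_model = build_modified_model(ModelConfig(family="se_resnet34", num_classes=7, rng_seed=3))
        plain = build_resnet(ModelConfig(family="resnet34", num_classes=7, rng_seed=99))
        for attr in ("stem_conv", "stem_bn", "fc"):
            src, dst = getattr(se_model, attr), getattr(plain, attr)
            for ps, pd in zip(src.parameters(), dst.parameters()):
                pd.data = ps.data.copy()
        for s_src, s_dst in zip(se_model.stages, plain.stages):
            for ps, pd in zip(s_src.parameters(), s_dst.parameters()):
                pd.data = ps.data.copy()
        se_model.attn_stem.forward = lambda x: x
        se_model.attn_conv2.forward = lambda x: x
        se_model.train(False)
        plain.train(False)
        x = np.random.default_rng(8).standard_normal((1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(se_model.forward(x), plain.forward(x), atol=1e-5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(family="resnet1001")


def test_all_families_forward_and_backward_on_224():
    """Smoke invariant: every family builds, forwards and backpropagates
    on a 224 x 224 x 3 batch."""
    x = np.random.default_rng(0).standard_normal((1, 3, 224, 224)).astype(np.float32)
    for family in ("resnet18", "resnet34", "resnet50", "resnet101",
                   "cbam_resnet34", "se_resnet34", "se_resnet34_dcn"):
        model = build_model(ModelConfig(family=family, num_classes=7, rng_seed=0))
        logits = model.forward(x)
        assert logits.shape == (1, 7)
        model.zero_grad()
        dx = model.backward(np.ones_like(logits, dtype=np.float32) / 7)
        assert dx.shape == x.shape
        assert np.isfinite(dx).all()
        assert any(np.abs(p.grad).max() > 0 for p in model.parameters())
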