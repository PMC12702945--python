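"""Network assembly, parameter/FLOP accounting and structural invariants."""

import numpy as np
import pytest

from enetcaem import nn
from enetcaem.blocks import BlockConfig
from enetcaem.network import (
    ArchitectureConfig,
    BaselineB0,
    ENetCAEM,
    ImprovedMBConv,
    MBConv,
    StageSpec,
    build_baseline_b0,
    build_enet_caem,
    complexity_report,
    count_flops,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from enetcaem.nn import Tensor


class TestParameterCounting:
    def test_plain_conv_count(self):
        conv = nn.Conv2d(2, 4, 3, bias=False)
        assert count_parameters(conv) == 3 * 3 * 2 * 4 == 72

    def test_linear_with_bias_count(self):
        assert count_parameters(nn.Linear(512, 8)) == 512 * 8 + 8 == 4104

    def test_counts_agree_with_brute_force_walk(self):
        net = build_enet_caem(ArchitectureConfig.enet_caem_small(), seed=0)
        walk = sum(int(np.prod(p.data.shape)) for _, p in net.named_parameters())
        assert count_parameters(net) == walk


class TestFlopCounting:
    def test_conv_closed_form(self):
        conv = nn.Conv2d(2, 4, 3, stride=1, padding=1, bias=False)
        assert count_flops_layer(conv, (1, 2, 8, 8)) == 3 * 3 * 2 * 4 * 8 * 8 == 4608

    def test_depthwise_closed_form(self):
        conv = nn.Conv2d(4, 4, 3, stride=1, padding=1, groups=4, bias=False)
        assert count_flops_layer(conv, (1, 4, 8, 8)) == 3 * 3 * 4 * 8 * 8 == 2304

    def test_three_layer_toy_recomputation(self):
        class Toy(nn.Module):
            def __init__(self):
                super().__init__()
                self.c1 = nn.Conv2d(3, 8, 3, stride=2, padding=1, bias=False)
                self.c2 = nn.Conv2d(8, 8, 3, padding=1, groups=8, bias=False)
                self.fc = nn.Linear(8, 5)

            def forward(self, x):
                h = self.c2(self.c1(x)).mean(axis=(2, 3))
                return self.fc(h)

        expected = 3 * 3 * 3 * 8 * 8 * 8 + 3 * 3 * 8 * 8 * 8 + 8 * 5
        assert count_flops(Toy(), (16, 16)) == expected


def count_flops_layer(layer, input_shape):
    with nn.mac_trace() as t:
        layer(Tensor(np.zeros(input_shape, dtype=np.float32)))
    return sum(t)


class TestBaselineB0:
    def test_parameter_count_and_block_tally(self):
        net = build_baseline_b0(num_classes=8, seed=0)
        assert round(count_parameters(net) / 1e6, 2) == pytest.approx(4.02, abs=0.05)
        n_blocks = sum(1 for m in net.modules() if isinstance(m, MBConv))
        assert n_blocks == 16

    def test_forward_logit_shape(self):
        net = build_baseline_b0(num_classes=8, seed=0).eval()
        out = net(Tensor(np.zeros((1, 3, 224, 224), dtype=np.float32)))
        assert out.shape == (1, 8)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_baseline_b0(num_classes=1)


class TestENetCAEM:
    def test_thirteen_blocks_and_finite_logits(self, rng):
        net = build_enet_caem(seed=0).eval()
        assert sum(1 for m in net.modules() if isinstance(m, ImprovedMBConv)) == 13
        out = net(Tensor(rng.normal(size=(2, 3, 224, 224)).astype(np.float32)))
        assert out.shape == (2, 8)
        assert np.isfinite(out.data).all()

    def test_repeat_sum_mismatch_rejected(self):
        cfg = ArchitectureConfig.enet_caem_default()
        cfg.stages[0].repeats += 1
        with pytest.raises(ValueError):
            build_enet_caem(cfg)

    def test_build_determinism(self):
        a = build_enet_caem(ArchitectureConfig.enet_caem_small(), seed=5)
        b = build_enet_caem(ArchitectureConfig.enet_caem_small(), seed=5)
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)
        x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 32, 32)).astype(np.float32))
        np.testing.assert_array_equal(a.eval()(x).data, b.eval()(x).data)

    def test_every_parameter_receives_gradient(self):
        from enetcaem.training import label_smoothing_ce

        cfg = ArchitectureConfig.enet_caem_small()
        cfg.block.eca_fusion = "learned"
        net = build_enet_caem(cfg, seed=1)
        net.seed_stochastic(2)
        g = np.random.default_rng(0)
        x = Tensor(g.normal(size=(8, 3, 32, 32)).astype(np.float32))
        labels = g.integers(0, 8, size=8)
        loss = label_smoothing_ce(net(x), labels, 0.1)
        loss.backward()
        missing = [
            name
            for name, p in net.named_parameters()
            if p.grad is None or not np.isfinite(p.grad).all()
        ]
        assert missing == []

    def test_ccm_strictly_increases_parameters(self):
        cfg_on = ArchitectureConfig.enet_caem_small()
        cfg_off = ArchitectureConfig.enet_caem_small()
        for s in cfg_off.stages:
            s.use_ccm = False
        p_on = count_parameters(build_enet_caem(cfg_on, seed=0))
        p_off = count_parameters(build_enet_caem(cfg_off, seed=0))
        assert p_on > p_off

    def test_multiscale_eca_cheaper_than_se(self):
        # same block geometry: the SE bottleneck (two dense 1x1 convs)
        # carries far more weights than three 1-D convs + one 7x7 conv
        rng = np.random.default_rng(0)
        se_block = MBConv(16, 16, 6, 3, 1, rng)
        eca_block = ImprovedMBConv(16, 16, 6, 3, 1, BlockConfig(), False, 0.0, rng)
        se_params = count_parameters(se_block.se)
        eca_params = count_parameters(eca_block.attention)
        assert eca_params < se_params


class TestImprovedMBConvContracts:
    def test_zero_projection_keeps_residual_identity(self, rng):
        block = ImprovedMBConv(8, 8, 3, 3, 1, BlockConfig(), False, 0.0, rng)
        block.project.layers[0].weight.data[...] = 0.0
        block.eval()
        x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(block(Tensor(x)).data, x, rtol=1e-5, atol=1e-6)

    def test_stride_two_halves_spatial_dims(self, rng):
        block = ImprovedMBConv(16, 24, 6, 3, 2, BlockConfig(), False, 0.0, rng)
        out = block(Tensor(rng.normal(size=(1, 16, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 24, 16, 16)

    def test_channel_mismatch_rejected(self, rng):
        block = ImprovedMBConv(16, 24, 6, 3, 1, BlockConfig(), False, 0.0, rng)
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32)))

    def test_expansion_width(self, rng):
        block = ImprovedMBConv(16, 24, 6, 3, 1, BlockConfig(), False, 0.0, rng)
        assert block.expand.layers[0].out_channels == 96


def test_checkpoint_roundtrip(tmp_path):
    cfg = ArchitectureConfig.enet_caem_small()
    net = build_enet_caem(cfg, seed=3)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(net, path, {"note": "test"})
    state, meta = load_checkpoint(path)
    assert meta == {"note": "test"}
    other = build_enet_caem(cfg, seed=4)
    other.load_state_dict(state)
    x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 32, 32)).astype(np.float32))
    np.testing.assert_array_equal(net.eval()(x).data, other.eval()(x).data)


def test_complexity_report_rounding():
    class TinyConvNet(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = nn.Conv2d(3, 4, 3, padding=1, bias=False)

        def forward(self, x):
            return self.conv(x)

    rep = complexity_report(TinyConvNet(), (8, 8))
    assert rep.params_millions == 0.0  # 108 params rounds to 0.00 M
    assert rep.flops_g == 0.0  # 6912 MACs rounds to 0.000 G
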