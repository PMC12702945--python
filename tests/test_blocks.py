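"""The five bespoke blocks: analytic limits, forced-weight traces,
oracle equivalence and the boundedness/contraction invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enetcaem import blocks, nn
from enetcaem.nn import Tensor

from oracles import (
    channel_attention_oracle,
    conv2d_oracle,
    mixed_pool_oracle,
    spatial_attention_oracle,
)


def zero_(module):
    for p in module.parameters():
        p.data[...] = 0.0
    return module


# ---- multi-scale channel attention -----------------------------------


class TestMultiScaleChannelAttention:
    def test_zero_weights_give_half_everywhere(self, rng):
        att = zero_(blocks.MultiScaleChannelAttention())
        w = att(Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32)))
        np.testing.assert_allclose(w.data, 0.5, atol=1e-7)
        assert w.shape == (2, 6, 1, 1)

    def test_identical_branches_equal_single_scale(self, rng):
        att3 = blocks.MultiScaleChannelAttention(kernel_sizes=(3, 3, 3))
        single = blocks.MultiScaleChannelAttention(kernel_sizes=(3,))
        shared_w = rng.normal(size=(1, 1, 3)).astype(np.float32)
        for conv in att3.branches.layers + single.branches.layers:
            conv.weight.data[...] = shared_w
            conv.bias.data[...] = 0.1
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(att3(x).data, single(x).data, rtol=1e-6)

    def test_center_tap_kernel_reads_channel_mean(self):
        # one branch, kernel (0, 1, 0): the pre-sigmoid response of each
        # channel is its own pooled mean
        att = blocks.MultiScaleChannelAttention(kernel_sizes=(3,))
        att.branches.layers[0].weight.data[...] = np.array([[[0.0, 1.0, 0.0]]])
        att.branches.layers[0].bias.data[...] = 0.0
        x = np.zeros((1, 4, 2, 2), dtype=np.float32)
        x[0, :, :, :] = np.arange(1, 5).reshape(4, 1, 1)
        w = att(Tensor(x))
        expected = 1.0 / (1.0 + np.exp(-np.array([1.0, 2.0, 3.0, 4.0])))
        np.testing.assert_allclose(w.data.reshape(4), expected, rtol=1e-6)

    def test_matches_explicit_sum_oracle(self, rng):
        att = blocks.MultiScaleChannelAttention(rng=rng)
        x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
        got = att(Tensor(x)).data.reshape(2, 8)
        want = channel_attention_oracle(
            x,
            [c.weight.data.reshape(-1) for c in att.branches.layers],
            [float(c.bias.data[0]) for c in att.branches.layers],
        )
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            blocks.MultiScaleChannelAttention(kernel_sizes=(3, 4))


# ---- spatial attention -----------------------------------------------


class TestSpatialAttention:
    def test_constant_channels_make_avg_equal_max(self, rng):
        x = np.broadcast_to(
            rng.normal(size=(2, 1, 5, 5)).astype(np.float32), (2, 4, 5, 5)
        ).copy()
        t = Tensor(x)
        np.testing.assert_allclose(
            t.mean(axis=1, keepdims=True).data, t.max(axis=1, keepdims=True).data, rtol=1e-6
        )

    def test_zero_conv_gives_half_map(self, rng):
        att = zero_(blocks.SpatialAttention())
        w = att(Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32)))
        np.testing.assert_allclose(w.data, 0.5, atol=1e-7)
        assert w.shape == (2, 1, 6, 6)

    def test_matches_nested_loop_oracle(self, rng):
        att = blocks.SpatialAttention(rng=rng)
        x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
        got = att(Tensor(x)).data
        want = spatial_attention_oracle(x, att.conv.weight.data, float(att.conv.bias.data[0]))
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)


# ---- composed ECA ----------------------------------------------------


class TestMultiScaleECA:
    def test_zero_weights_scale_input_by_quarter(self, rng):
        eca = zero_(blocks.MultiScaleECA())
        x = rng.normal(size=(2, 5, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(eca(Tensor(x)).data, 0.25 * x, rtol=1e-6, atol=1e-7)

    def test_saturated_weights_approach_identity(self, rng):
        eca = zero_(blocks.MultiScaleECA())
        for conv in eca.channel.branches.layers:
            conv.bias.data[...] = 50.0  # sigmoid -> 1
        eca.spatial.conv.bias.data[...] = 50.0
        x = rng.normal(size=(1, 4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(eca(Tensor(x)).data, x, rtol=1e-5, atol=1e-6)

    def test_never_amplifies(self, rng):
        eca = blocks.MultiScaleECA(rng=rng)
        x = rng.normal(size=(2, 7, 6, 6)).astype(np.float32) * 10
        out = eca(Tensor(x)).data
        assert (np.abs(out) <= np.abs(x) + 1e-6).all()


# ---- channel context module ------------------------------------------


class TestChannelContextModule:
    def test_forced_zero_expansion_scales_by_half(self, rng):
        ccm = blocks.ChannelContextModule(6, reduction=2, rng=rng)
        ccm.expand.weight.data[...] = 0.0
        ccm.eval()  # bn2 at identity: zero running stats, gamma 1, beta 0
        x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(ccm(Tensor(x)).data, 0.5 * x, rtol=1e-6)

    def test_weights_constant_across_space(self, rng):
        ccm = blocks.ChannelContextModule(8, reduction=4, rng=rng)
        w = ccm.channel_weights(Tensor(rng.normal(size=(2, 8, 5, 7)).astype(np.float32)))
        assert w.shape == (2, 8, 1, 1)
        assert ((w.data >= 0) & (w.data <= 1)).all()

    @pytest.mark.parametrize("channels,reduction,hidden", [(32, 16, 2), (8, 16, 1), (64, 4, 16)])
    def test_hidden_width_floor_rule(self, channels, reduction, hidden):
        ccm = blocks.ChannelContextModule(channels, reduction)
        assert ccm.hidden == hidden

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            blocks.ChannelContextModule(8, reduction=0)


# ---- LightASPP -------------------------------------------------------


class TestLightASPP:
    def test_output_channel_count(self, rng):
        aspp = blocks.LightASPP(16, branch_channels=128, gap_channels=128, rng=rng)
        out = aspp(Tensor(rng.normal(size=(1, 16, 7, 7)).astype(np.float32)))
        assert out.shape == (1, 512, 7, 7)

    def test_global_branch_spatially_constant(self, rng):
        aspp = blocks.LightASPP(4, branch_channels=8, gap_channels=8, rng=rng)
        out = aspp(Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))).data
        gap_part = out[:, 24:, :, :]  # last gap_channels channels
        assert np.ptp(gap_part, axis=(2, 3)).max() < 1e-6

    def test_dilated_branch_matches_nested_loop_oracle(self, rng):
        aspp = blocks.LightASPP(2, branch_channels=3, gap_channels=2, rng=rng)
        aspp.eval()  # BN at identity running stats
        x = rng.normal(size=(1, 2, 9, 9)).astype(np.float32)
        out = aspp(Tensor(x)).data
        w = aspp.branches.layers[0].layers[0].weight.data  # rate-3 branch conv
        want = np.maximum(conv2d_oracle(x, w, None, stride=1, padding=3, dilation=3), 0.0)
        np.testing.assert_allclose(out[:, :3], want, rtol=1e-4, atol=1e-5)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            blocks.LightASPP(4, rates=(0, 3, 6))


# ---- mixed pooling ---------------------------------------------------


class TestMixedPool:
    def test_lambda_limits_reduce_to_pure_pooling(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        mx = blocks.mixed_pool(x, 1.0, mode="window", window=2, stride=2)
        av = blocks.mixed_pool(x, 0.0, mode="window", window=2, stride=2)
        np.testing.assert_allclose(mx.data, nn.max_pool2d(x, 2, 2).data, rtol=1e-6)
        np.testing.assert_allclose(av.data, nn.avg_pool2d(x, 2, 2).data, rtol=1e-6)

    def test_known_window_value(self):
        x = Tensor(np.array([1.0, 2.0, 3.0, 4.0], dtype=np.float32).reshape(1, 1, 2, 2))
        out = blocks.mixed_pool(x, 0.5, mode="window", window=2, stride=2)
        assert out.data.reshape(()) == pytest.approx(3.25)

    def test_matches_per_window_oracle(self, rng):
        x = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        got = blocks.mixed_pool(Tensor(x), 0.3, mode="window", window=2, stride=2).data
        want = mixed_pool_oracle(x, 0.3, 2, 2)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_monotone_in_lambda(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
        prev = None
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            cur = blocks.mixed_pool(x, lam, mode="global").data
            if prev is not None:
                assert (cur >= prev - 1e-6).all()
            prev = cur

    def test_output_between_min_and_max(self, rng):
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        out = blocks.mixed_pool(Tensor(x), 0.7, mode="global").data
        assert (out <= x.max(axis=(2, 3), keepdims=True) + 1e-6).all()
        assert (out >= x.min(axis=(2, 3), keepdims=True) - 1e-6).all()

    def test_oversized_window_rejected(self, rng):
        with pytest.raises(ValueError):
            blocks.mixed_pool(
                Tensor(np.zeros((1, 1, 4, 4), np.float32)), 0.5, mode="window", window=8
            )

    def test_module_keeps_lambda_in_unit_interval(self):
        pool = blocks.MixedPool(0.5)
        pool.lambda_logit.data[...] = 40.0
        assert 0.0 <= pool.lam <= 1.0
        pool.lambda_logit.data[...] = -40.0
        assert 0.0 <= pool.lam <= 1.0


# ---- learnable drop-path ---------------------------------------------


class TestLearnableDropPath:
    def test_eval_mode_is_identity(self, rng):
        dp = blocks.LearnableDropPath(0.1).eval()
        x = rng.normal(size=(4, 3, 2, 2)).astype(np.float32)
        np.testing.assert_array_equal(dp(Tensor(x)).data, x)

    def test_vanishing_probability_is_identity_in_training(self, rng):
        x = rng.normal(size=(4, 3, 2, 2)).astype(np.float32)
        theta = Tensor(np.float32(-60.0))  # p -> 0
        out = blocks.learnable_droppath(
            Tensor(x), theta, p_max=0.2, training=True, rng=np.random.default_rng(0)
        )
        np.testing.assert_allclose(out.data, x, rtol=1e-6)

    def test_monte_carlo_expectation_is_identity(self):
        # p = 0.5: gate/(1-p) has mean 1; check the sample mean over 10^4
        # draws stays within 3 standard errors
        B = 10_000
        # theta = 0 with p_max just below 1 puts the drop probability at 0.5
        x = np.ones((B, 1, 1, 1), dtype=np.float32)
        out = blocks.learnable_droppath(
            Tensor(x), Tensor(np.float32(0.0)), p_max=0.99999, training=True,
            rng=np.random.default_rng(99),
        )
        # p = sigmoid(0) * p_max ~= 0.5; keep prob 1-p, scale 1/(1-p)
        keep = 1.0 - 0.5 * 0.99999
        se = np.sqrt((1 - keep) / keep / B)
        assert abs(out.data.mean() - 1.0) < 3 * se

    def test_invalid_pmax_rejected(self, rng):
        with pytest.raises(ValueError):
            blocks.learnable_droppath(
                Tensor(np.zeros((1, 1, 1, 1), np.float32)),
                Tensor(np.float32(0.0)),
                p_max=1.0,
                training=True,
                rng=np.random.default_rng(0),
            )

    def test_theta_receives_gradient_through_rescaling(self):
        dp = blocks.LearnableDropPath(0.1)
        dp.set_rng(np.random.default_rng(3))
        x = Tensor(np.ones((16, 2, 2, 2), dtype=np.float32))
        dp(x).sum().backward()
        assert dp.theta.grad is not None and np.isfinite(dp.theta.grad).all()
        assert abs(float(dp.theta.grad)) > 0


# ---- cross-block invariants ------------------------------------------


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    b=st.integers(1, 2),
    c=st.integers(1, 8),
    h=st.sampled_from([1, 7, 8]),
    w=st.sampled_from([1, 7, 8]),
    seed=st.integers(0, 10_000),
)
def test_attention_weights_bounded_and_shapes_preserved(b, c, h, w, seed):
    g = np.random.default_rng(seed)
    x = Tensor(g.normal(size=(b, c, h, w)).astype(np.float32) * 5)
    eca = blocks.MultiScaleECA(rng=g)
    wc = eca.channel(x)
    assert wc.shape == (b, c, 1, 1) and ((wc.data >= 0) & (wc.data <= 1)).all()
    ws = eca.spatial(x)
    assert ws.shape == (b, 1, h, w) and ((ws.data >= 0) & (ws.data <= 1)).all()
    out = eca(x)
    assert out.shape == x.shape
    assert (np.abs(out.data) <= np.abs(x.data) + 1e-6).all()
    ccm = blocks.ChannelContextModule(c, 16, rng=g)
    cw = ccm.channel_weights(x)
    assert ((cw.data >= 0) & (cw.data <= 1)).all()
    out2 = ccm(x)
    assert out2.shape == x.shape
    assert (np.abs(out2.data) <= np.abs(x.data) + 1e-6).all()
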