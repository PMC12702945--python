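"""The model's bespoke computational blocks.

Five units, each independently testable on small feature maps:

* :class:`MultiScaleChannelAttention` — channel attention from parallel 1-D
  convolutions (kernels 3/5/7) over the globally pooled channel sequence,
  fused by averaging and squashed by a sigmoid.
* :class:`SpatialAttention` — channel-wise average+max maps, a 7x7
  convolution and a sigmoid, producing one spatial weight map.
* :class:`MultiScaleECA` — the two above composed: (x * Wc) * Ws.
* :class:`ChannelContextModule` — an SE-style bottleneck (1x1 conv down to
  C/r, BN, ReLU, 1x1 conv back up, BN, sigmoid) recalibrating channels.
* :class:`LightASPP` — three 3x3 dilated branches (rates 3/6/9, BN+ReLU)
  plus a pooled 1x1-conv global branch, concatenated without a fusion conv.
* :class:`MixedPool` / :func:`mixed_pool` — learnable blend
  y = lam * max + (1 - lam) * avg, lam kept in [0, 1] by a sigmoid
  reparameterisation.
* :class:`LearnableDropPath` / :func:`learnable_droppath` — stochastic
  depth whose drop probability p = sigmoid(theta) * p_max is trained.

All attention weights lie in [0, 1], so the attention blocks can only
shrink activations, never grow them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BlockConfig",
    "MultiScaleChannelAttention",
    "SpatialAttention",
    "MultiScaleECA",
    "ChannelContextModule",
    "LightASPP",
    "MixedPool",
    "mixed_pool",
    "LearnableDropPath",
    "learnable_droppath",
]


@dataclass
class BlockConfig:
    """Hyperparameters of the bespoke blocks (YAML-serialisable)."""

    eca_kernel_sizes: tuple = (3, 5, 7)
    eca_fusion: str = "mean"  # "mean" (default) or "learned" softmax branch weights
    ccm_reduction: int = 16
    aspp_rates: tuple = (3, 6, 9)
    aspp_branch_channels: int = 128
    aspp_gap_channels: int = 128
    mixed_pool_lambda_init: float = 0.5
    droppath_p_init: float = 0.0
    droppath_p_max: float = 0.2

    def __post_init__(self):
        if any(k % 2 == 0 or k < 1 for k in self.eca_kernel_sizes):
            raise ValueError("ECA kernel sizes must be odd and >= 1")
        if self.ccm_reduction < 1:
            raise ValueError("CCM reduction ratio must be a positive integer")
        if any(r <= 0 for r in self.aspp_rates):
            raise ValueError("ASPP dilation rates must be positive")
        if list(self.aspp_rates) != sorted(set(self.aspp_rates)):
            raise ValueError("ASPP dilation rates must be strictly increasing")
        if not 0.0 <= self.mixed_pool_lambda_init <= 1.0:
            raise ValueError("mixed-pool lambda init must lie in [0, 1]")
        if not 0.0 <= self.droppath_p_init < 1.0:
            raise ValueError("DropPath p init must lie in [0, 1)")
        if not 0.0 < self.droppath_p_max < 1.0:
            raise ValueError("DropPath p_max must lie in (0, 1)")


def _check_4d(x: Tensor):
    if x.ndim != 4 or min(x.shape) < 1:
        raise ValueError(f"expected a B x C x H x W feature map, got shape {x.shape}")


class MultiScaleChannelAttention(nn.Module):
    """Channel weights from parallel 1-D convolutions at several scales.

    The input is globally average-pooled to one scalar per channel, the
    channel vector is treated as a length-C sequence with a single feature
    channel, and each branch convolves it with an odd kernel (padding
    (k-1)/2 keeps length C). Branch outputs are fused by the arithmetic
    mean — or, optionally, by learned softmax weights — and a sigmoid maps
    the fusion to per-channel weights in (0, 1).
    """

    def __init__(
        self,
        kernel_sizes: tuple = (3, 5, 7),
        fusion: str = "mean",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if any(k % 2 == 0 or k < 1 for k in kernel_sizes):
            raise ValueError("kernel sizes must be odd and >= 1")
        if fusion not in ("mean", "learned"):
            raise ValueError("fusion must be 'mean' or 'learned'")
        rng = rng or np.random.default_rng(0)
        self.kernel_sizes = tuple(kernel_sizes)
        self.fusion = fusion
        self.branches = nn.Sequential(
            *[
                nn.Conv1d(1, 1, k, padding=(k - 1) // 2, bias=True, rng=rng)
                for k in kernel_sizes
            ]
        )
        if fusion == "learned":
            self.fusion_logits = Tensor(
                np.zeros(len(kernel_sizes), dtype=np.float32), requires_grad=True
            )

    def forward(self, x: Tensor) -> Tensor:
        _check_4d(x)
        B, C = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3), keepdims=True)  # B x C x 1 x 1
        seq = pooled.reshape(B, 1, C)  # channel sequence
        outs = [conv(seq) for conv in self.branches.layers]  # each B x 1 x C
        if self.fusion == "learned":
            w = nn.log_softmax(self.fusion_logits, axis=0).exp()
            stacked = nn.concat(outs, axis=1)  # B x n x C
            fused = (stacked * w.reshape(1, len(outs), 1)).sum(axis=1, keepdims=True)
        else:
            acc = outs[0]
            for o in outs[1:]:
                acc = acc + o
            fused = acc * (1.0 / len(outs))
        return fused.sigmoid().reshape(B, C, 1, 1)


class SpatialAttention(nn.Module):
    """One spatial weight map from channel-pooled statistics.

    Average and max over the channel axis give a 2-channel map; a 7x7
    convolution (padding 3) mixes the two into a single channel and a
    sigmoid bounds it in (0, 1).
    """

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 7, padding=3, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_4d(x)
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(nn.concat([avg, mx], axis=1)).sigmoid()


class MultiScaleECA(nn.Module):
    """Multi-scale channel attention followed by spatial attention.

    Output = (x * Wc) * Ws, with Wc broadcast over space and Ws over
    channels. Both weight factors are in [0, 1], so every activation's
    magnitude can only shrink.
    """

    def __init__(
        self,
        kernel_sizes: tuple = (3, 5, 7),
        fusion: str = "mean",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.channel = MultiScaleChannelAttention(kernel_sizes, fusion=fusion, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        xp = x * self.channel(x)
        return xp * self.spatial(xp)


class ChannelContextModule(nn.Module):
    """SE-style channel recalibration with batch-normed 1x1 bottleneck.

    GAP -> 1x1 conv to max(C // r, 1) channels -> BN -> ReLU -> 1x1 conv
    back to C -> BN -> sigmoid; the resulting per-channel weights multiply
    the input. The weights are constant across space (GAP collapses H, W).
    """

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction ratio must be a positive integer")
        if channels < 1:
            raise ValueError("channel count must be >= 1")
        hidden = max(channels // reduction, 1)
        self.channels, self.reduction, self.hidden = channels, reduction, hidden
        self.squeeze = nn.Conv2d(channels, hidden, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(hidden)
        self.expand = nn.Conv2d(hidden, channels, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def channel_weights(self, x: Tensor) -> Tensor:
        _check_4d(x)
        z = x.mean(axis=(2, 3), keepdims=True)
        z = self.bn1(self.squeeze(z)).relu()
        z = self.bn2(self.expand(z))
        return z.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.channel_weights(x)


class LightASPP(nn.Module):
    """Lightweight atrous spatial pyramid pooling.

    Three 3x3 dilated convolutions (padding = rate preserves H x W), each
    with BN + ReLU, run in parallel with a global-average-pool branch that
    is compressed to ``gap_channels`` by a 1x1 conv (BN + ReLU) and
    bilinearly upsampled back to H x W — interpolation of a 1x1 map is a
    constant fill. The four feature stacks are concatenated directly, so
    the output has 3 * branch_channels + gap_channels channels.
    """

    def __init__(
        self,
        in_channels: int,
        rates: tuple = (3, 6, 9),
        branch_channels: int = 128,
        gap_channels: int = 128,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if any(r <= 0 for r in rates):
            raise ValueError("dilation rates must be positive")
        rng = rng or np.random.default_rng(0)
        self.rates = tuple(rates)
        self.out_channels = len(rates) * branch_channels + gap_channels
        self.branches = nn.Sequential(
            *[
                nn.Sequential(
                    nn.Conv2d(
                        in_channels, branch_channels, 3, padding=r, dilation=r, bias=False, rng=rng
                    ),
                    nn.BatchNorm2d(branch_channels),
                    nn.ReLU(),
                )
                for r in rates
            ]
        )
        self.gap_conv = nn.Conv2d(in_channels, gap_channels, 1, bias=False, rng=rng)
        self.gap_bn = nn.BatchNorm2d(gap_channels)

    def forward(self, x: Tensor) -> Tensor:
        _check_4d(x)
        B, C, H, W = x.shape
        feats = [branch(x) for branch in self.branches.layers]
        g = x.mean(axis=(2, 3), keepdims=True)
        g = self.gap_bn(self.gap_conv(g)).relu()
        feats.append(g.broadcast_to((B, g.shape[1], H, W)))
        return nn.concat(feats, axis=1)


def mixed_pool(
    x: Tensor,
    lam,
    mode: str = "global",
    window: int | None = None,
    stride: int | None = None,
) -> Tensor:
    """Learnable blend of max and average pooling.

    y = lam * max_pool(x) + (1 - lam) * avg_pool(x), per window in
    ``window`` mode or over all of H x W in ``global`` mode. ``lam`` may
    be a float in [0, 1] or a scalar Tensor (the learnable case).
    """
    _check_4d(x)
    if not isinstance(lam, Tensor):
        if not 0.0 <= float(lam) <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lam = Tensor(np.float32(lam))
    if mode == "global":
        mx = x.max(axis=2, keepdims=True).max(axis=3, keepdims=True)
        av = x.mean(axis=(2, 3), keepdims=True)
    elif mode == "window":
        if window is None:
            raise ValueError("window mode requires a window size")
        mx = nn.max_pool2d(x, window, stride)
        av = nn.avg_pool2d(x, window, stride)
    else:
        raise ValueError("mode must be 'global' or 'window'")
    return lam * mx + (1.0 - lam) * av


class MixedPool(nn.Module):
    """Mixed pooling with a trainable blend weight.

    The blend weight lam is stored as a logit and squashed by a sigmoid so
    it stays in [0, 1] throughout training.
    """

    def __init__(
        self,
        lambda_init: float = 0.5,
        mode: str = "global",
        window: int | None = None,
        stride: int | None = None,
    ):
        super().__init__()
        if not 0.0 <= lambda_init <= 1.0:
            raise ValueError("lambda init must lie in [0, 1]")
        eps = 1e-6
        logit = float(np.log((lambda_init + eps) / (1.0 - lambda_init + eps)))
        self.lambda_logit = Tensor(np.float32(logit), requires_grad=True)
        self.mode, self.window, self.stride = mode, window, stride

    @property
    def lam(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.lambda_logit.data)))

    def forward(self, x: Tensor) -> Tensor:
        return mixed_pool(
            x, self.lambda_logit.sigmoid(), mode=self.mode, window=self.window, stride=self.stride
        )


def learnable_droppath(
    x: Tensor,
    theta: Tensor,
    p_max: float,
    training: bool,
    rng: np.random.Generator,
) -> Tensor:
    """Stochastic depth with a trainable drop probability.

    p = sigmoid(theta) * p_max. In training, each sample's residual branch
    is kept with probability 1 - p and rescaled by 1 / (1 - p), so the
    expectation equals the eval-mode output (the identity). The gradient
    reaches theta through the rescaling factor.
    """
    if not 0.0 < p_max < 1.0:
        raise ValueError("p_max must lie in (0, 1)")
    if not training:
        return x
    p = theta.sigmoid() * p_max
    B = x.shape[0]
    gate = (rng.random(B) >= p.data).astype(np.float32).reshape(B, 1, 1, 1)
    scale = (1.0 - p) ** -1.0
    return x * Tensor(gate) * scale


class LearnableDropPath(nn.Module):
    """Module wrapper holding theta and a seedable generator."""

    def __init__(self, p_init: float = 0.0, p_max: float = 0.2):
        super().__init__()
        if not 0.0 <= p_init < 1.0:
            raise ValueError("initial drop probability must lie in [0, 1)")
        if not 0.0 < p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")
        frac = np.clip(p_init / p_max, 1e-4, 1.0 - 1e-4)
        self.theta = Tensor(np.float32(np.log(frac / (1.0 - frac))), requires_grad=True)
        self.p_max = p_max
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator):
        object.__setattr__(self, "_rng", rng)

    @property
    def p(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.theta.data)) * self.p_max)

    def forward(self, x: Tensor) -> Tensor:
        return learnable_droppath(x, self.theta, self.p_max, self.training, self._rng)
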