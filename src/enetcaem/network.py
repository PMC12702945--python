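"""Backbone assembly and complexity accounting.

Two builds are provided:

* :func:`build_baseline_b0` — the standard EfficientNet-B0 classifier
  (stem, seven MBConv stages with squeeze-and-excitation, 1x1-to-1280
  head, fully connected layer), totalling 16 MBConv blocks.
* :func:`build_enet_caem` — the modified network: 13 improved MBConv
  blocks in which SE is replaced by multi-scale ECA (+ spatial attention),
  a channel context module is inserted after the depthwise convolution in
  the three middle stages, residuals pass through learnable drop-path, and
  the classification head is LightASPP -> global mixed pooling -> dropout
  -> fully connected.

Complexity accounting reports trainable parameters (millions) and
multiply-accumulate operations (units of 1e9 at batch 1; convolution,
depthwise and linear layers only — BN, activations and pooling excluded,
the convention under which compact CNNs are usually quoted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .blocks import (
    BlockConfig,
    ChannelContextModule,
    LearnableDropPath,
    LightASPP,
    MixedPool,
    MultiScaleECA,
)

__all__ = [
    "StageSpec",
    "HeadConfig",
    "ArchitectureConfig",
    "ComplexityReport",
    "build_baseline_b0",
    "build_enet_caem",
    "count_parameters",
    "count_flops",
    "complexity_report",
    "save_checkpoint",
    "load_checkpoint",
    "BaselineB0",
    "ENetCAEM",
]

# EfficientNet-B0 MBConv stage layout (stages 2-8 of the nine-stage net):
# (expansion, kernel, stride, out_channels, repeats)
_B0_STAGES = [
    (1, 3, 1, 16, 1),
    (6, 3, 2, 24, 2),
    (6, 5, 2, 40, 2),
    (6, 3, 2, 80, 3),
    (6, 5, 1, 112, 3),
    (6, 5, 2, 192, 4),
    (6, 3, 1, 320, 1),
]

# Repeats profile of the reduced 13-block variant; fixed by the
# calibration documented in docs/methods.md (scripts/calibrate_architecture.py).
_ENET_REPEATS = (1, 1, 2, 3, 1, 4, 1)
# Dilated-branch width of LightASPP fixed by the same calibration.
_ENET_ASPP_BRANCH_CHANNELS = 94
_ENET_RETAIN_1X1_EXPAND = True


@dataclass
class StageSpec:
    """One MBConv stage: the first block may stride, repeats keep stride 1."""

    expansion: int
    kernel: int
    stride: int
    out_channels: int
    repeats: int
    use_ccm: bool = False

    def __post_init__(self):
        if self.expansion < 1 or self.kernel % 2 == 0 or self.stride not in (1, 2):
            raise ValueError("invalid stage spec")
        if self.out_channels < 1 or self.repeats < 1:
            raise ValueError("invalid stage spec")


@dataclass
class HeadConfig:
    retain_1x1_expand: bool = _ENET_RETAIN_1X1_EXPAND
    dropout_rate: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass
class ArchitectureConfig:
    """Declarative description of the reduced-backbone network."""

    stages: list = field(default_factory=list)
    num_classes: int = 8
    input_size: tuple = (224, 224)
    head: HeadConfig = field(default_factory=HeadConfig)
    block: BlockConfig = field(default_factory=BlockConfig)
    total_mbconv_blocks: int = 13

    @classmethod
    def enet_caem_default(cls, num_classes: int = 8) -> "ArchitectureConfig":
        """The calibrated 13-block profile."""
        stages = []
        for (e, k, s, c, _), r in zip(_B0_STAGES, _ENET_REPEATS):
            stages.append(StageSpec(e, k, s, c, r, use_ccm=c in (40, 80, 112)))
        return cls(
            stages=stages,
            num_classes=num_classes,
            block=BlockConfig(aspp_branch_channels=_ENET_ASPP_BRANCH_CHANNELS),
        )

    @classmethod
    def enet_caem_small(cls, num_classes: int = 8, input_size: tuple = (32, 32)) -> "ArchitectureConfig":
        """A width- and resolution-reduced profile of the same architecture.

        Keeps all 13 blocks and every block type (CCM, multi-scale ECA,
        LightASPP head, mixed pooling, drop-path) but shrinks channel
        widths so that CPU training runs at desk scale. Used for the
        learnability checks on synthetic data.
        """
        widths = (12, 16, 24, 32, 48, 64, 96)
        stages = []
        for i, ((e, k, s, _, _), r, c) in enumerate(zip(_B0_STAGES, _ENET_REPEATS, widths)):
            stages.append(StageSpec(min(e, 4), k, s, c, r, use_ccm=i in (2, 3, 4)))
        return cls(
            stages=stages,
            num_classes=num_classes,
            input_size=input_size,
            head=HeadConfig(retain_1x1_expand=False),
            block=BlockConfig(
                aspp_branch_channels=32, aspp_gap_channels=32, ccm_reduction=4
            ),
        )

    def validate(self):
        total = sum(s.repeats for s in self.stages)
        if total != self.total_mbconv_blocks:
            raise ValueError(
                f"stage repeats sum to {total}, expected {self.total_mbconv_blocks}"
            )
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["block"]["eca_kernel_sizes"] = list(self.block.eca_kernel_sizes)
        d["block"]["aspp_rates"] = list(self.block.aspp_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        stages = [StageSpec(**s) for s in d.get("stages", [])]
        block = d.get("block", {})
        block = BlockConfig(
            **{
                **block,
                "eca_kernel_sizes": tuple(block.get("eca_kernel_sizes", (3, 5, 7))),
                "aspp_rates": tuple(block.get("aspp_rates", (3, 6, 9))),
            }
        )
        return cls(
            stages=stages,
            num_classes=int(d.get("num_classes", 8)),
            input_size=tuple(d.get("input_size", (224, 224))),
            head=HeadConfig(**d.get("head", {})),
            block=block,
            total_mbconv_blocks=int(d.get("total_mbconv_blocks", 13)),
        )


@dataclass
class ComplexityReport:
    params_millions: float
    flops_g: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ---- building blocks -------------------------------------------------


class SqueezeExcite(nn.Module):
    """Classic SE: GAP -> 1x1 down (Swish) -> 1x1 up (sigmoid) -> scale.

    Hidden width is a quarter of the block *input* channels (the B0
    convention), not of the expanded width.
    """

    def __init__(self, channels: int, se_channels: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(channels, se_channels, 1, bias=True, rng=rng)
        self.expand = nn.Conv2d(se_channels, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.expand(self.reduce(s).swish()).sigmoid()
        return x * s


class MBConv(nn.Module):
    """Baseline inverted residual block with squeeze-and-excitation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        expansion: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        mid = in_channels * expansion
        self.use_residual = stride == 1 and in_channels == out_channels
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(in_channels, mid, 1, bias=False, rng=rng),
                nn.BatchNorm2d(mid),
                nn.Swish(),
            )
        else:
            self.expand = nn.Identity()
        self.depthwise = nn.Sequential(
            nn.Conv2d(
                mid, mid, kernel, stride=stride, padding=(kernel - 1) // 2,
                groups=mid, bias=False, rng=rng,
            ),
            nn.BatchNorm2d(mid),
            nn.Swish(),
        )
        self.se = SqueezeExcite(mid, max(1, in_channels // 4), rng)
        self.project = nn.Sequential(
            nn.Conv2d(mid, out_channels, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out_channels),
        )

    def forward(self, x: Tensor) -> Tensor:
        out = self.project(self.se(self.depthwise(self.expand(x))))
        if self.use_residual:
            out = out + x
        return out


class ImprovedMBConv(nn.Module):
    """Modified inverted residual: CCM (optional) + multi-scale ECA,
    residual gated by learnable drop-path."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        expansion: int,
        kernel: int,
        stride: int,
        blockcfg: BlockConfig,
        use_ccm: bool,
        droppath_p_init: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        mid = in_channels * expansion
        self.in_channels, self.stride = in_channels, stride
        self.use_residual = stride == 1 and in_channels == out_channels
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(in_channels, mid, 1, bias=False, rng=rng),
                nn.BatchNorm2d(mid),
                nn.Swish(),
            )
        else:
            self.expand = nn.Identity()
        self.depthwise = nn.Sequential(
            nn.Conv2d(
                mid, mid, kernel, stride=stride, padding=(kernel - 1) // 2,
                groups=mid, bias=False, rng=rng,
            ),
            nn.BatchNorm2d(mid),
            nn.Swish(),
        )
        self.ccm = (
            ChannelContextModule(mid, blockcfg.ccm_reduction, rng=rng)
            if use_ccm
            else nn.Identity()
        )
        self.attention = MultiScaleECA(
            blockcfg.eca_kernel_sizes, fusion=blockcfg.eca_fusion, rng=rng
        )
        self.project = nn.Sequential(
            nn.Conv2d(mid, out_channels, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out_channels),
        )
        if self.use_residual:
            self.droppath = LearnableDropPath(droppath_p_init, blockcfg.droppath_p_max)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        out = self.attention(self.ccm(self.depthwise(self.expand(x))))
        out = self.project(out)
        if self.use_residual:
            out = self.droppath(out) + x
        return out


class BaselineB0(nn.Module):
    """Standard EfficientNet-B0 classifier."""

    def __init__(self, num_classes: int = 8, rng: np.random.Generator | None = None):
        super().__init__()
        if num_classes < 2:
            raise ValueError("need at least two classes")
        rng = rng or np.random.default_rng(0)
        self.stem = nn.Sequential(
            nn.Conv2d(3, 32, 3, stride=2, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(32),
            nn.Swish(),
        )
        blocks = []
        cin = 32
        for e, k, s, c, r in _B0_STAGES:
            for i in range(r):
                blocks.append(MBConv(cin, c, e, k, s if i == 0 else 1, rng))
                cin = c
        self.blocks = nn.Sequential(*blocks)
        self.head_conv = nn.Sequential(
            nn.Conv2d(320, 1280, 1, bias=False, rng=rng),
            nn.BatchNorm2d(1280),
            nn.Swish(),
        )
        self.dropout = nn.Dropout(0.2)
        self.fc = nn.Linear(1280, num_classes, rng=rng)
        self.num_classes = num_classes

    def forward(self, x: Tensor) -> Tensor:
        h = self.head_conv(self.blocks(self.stem(x)))
        h = h.mean(axis=(2, 3))  # global average pool -> B x 1280
        return self.fc(self.dropout(h))


class ENetCAEM(nn.Module):
    """Reduced-backbone network with multi-scale attention head."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.stem = nn.Sequential(
            nn.Conv2d(3, 32, 3, stride=2, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(32),
            nn.Swish(),
        )
        n_blocks = sum(s.repeats for s in cfg.stages)
        blocks = []
        cin = 32
        idx = 0
        for s in cfg.stages:
            for i in range(s.repeats):
                # drop probability ramps linearly 0 -> 0.1 with depth
                p_init = 0.1 * idx / max(n_blocks - 1, 1)
                blocks.append(
                    ImprovedMBConv(
                        cin,
                        s.out_channels,
                        s.expansion,
                        s.kernel,
                        s.stride if i == 0 else 1,
                        cfg.block,
                        s.use_ccm,
                        p_init,
                        rng,
                    )
                )
                cin = s.out_channels
                idx += 1
        self.blocks = nn.Sequential(*blocks)
        if cfg.head.retain_1x1_expand:
            self.head_conv = nn.Sequential(
                nn.Conv2d(cin, 1280, 1, bias=False, rng=rng),
                nn.BatchNorm2d(1280),
                nn.Swish(),
            )
            cin = 1280
        else:
            self.head_conv = nn.Identity()
        self.aspp = LightASPP(
            cin,
            rates=cfg.block.aspp_rates,
            branch_channels=cfg.block.aspp_branch_channels,
            gap_channels=cfg.block.aspp_gap_channels,
            rng=rng,
        )
        self.pool = MixedPool(cfg.block.mixed_pool_lambda_init, mode="global")
        self.dropout = nn.Dropout(cfg.head.dropout_rate)
        self.fc = nn.Linear(self.aspp.out_channels, cfg.num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.aspp(self.head_conv(self.blocks(self.stem(x))))
        h = self.pool(h)  # B x C x 1 x 1
        h = h.reshape(h.shape[0], h.shape[1])
        return self.fc(self.dropout(h))

    def seed_stochastic(self, seed: int):
        """Give every dropout / drop-path module an independent seeded rng."""
        ss = np.random.SeedSequence(seed)
        stochastic = [
            m
            for m in self.modules()
            if isinstance(m, (nn.Dropout, LearnableDropPath))
        ]
        for m, child in zip(stochastic, ss.spawn(len(stochastic))):
            m.set_rng(np.random.default_rng(child))


def build_baseline_b0(num_classes: int = 8, seed: int = 0) -> BaselineB0:
    return BaselineB0(num_classes, rng=np.random.default_rng(seed))


def build_enet_caem(
    cfg: ArchitectureConfig | None = None, seed: int = 0
) -> ENetCAEM:
    cfg = cfg or ArchitectureConfig.enet_caem_default()
    return ENetCAEM(cfg, rng=np.random.default_rng(seed))


# ---- complexity accounting -------------------------------------------


def count_parameters(net: nn.Module) -> int:
    """Number of trainable scalar parameters."""
    return sum(p.data.size for p in net.parameters())


def count_flops(net: nn.Module, input_size: tuple = (224, 224)) -> int:
    """Multiply-accumulates of one forward pass at batch 1.

    Counts convolution, depthwise and linear layers only (MAC convention);
    batch norm, activations and pooling are excluded.
    """
    was_training = net.training
    net.eval()
    x = Tensor(np.zeros((1, 3, input_size[0], input_size[1]), dtype=np.float32))
    with nn.mac_trace() as trace:
        net(x)
    if was_training:
        net.train()
    return int(sum(trace))


def complexity_report(net: nn.Module, input_size: tuple = (224, 224)) -> ComplexityReport:
    return ComplexityReport(
        params_millions=round(count_parameters(net) / 1e6, 2),
        flops_g=round(count_flops(net, input_size) / 1e9, 3),
    )


# ---- checkpoints -----------------------------------------------------


def save_checkpoint(net: nn.Module, path: str, config: dict | None = None):
    """Serialise weights (and an embedded JSON config) to an .npz file."""
    state = net.state_dict()
    meta = json.dumps(config or {})
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple[dict, dict]:
    """Return (state_dict, config dict) from an .npz checkpoint."""
    with np.load(path) as z:
        state = {k: z[k] for k in z.files if k != "__config__"}
        config = json.loads(z["__config__"].tobytes().decode()) if "__config__" in z.files else {}
    return state, config
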