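"""YAML run configuration.

One file describes the architecture hyperparameters and the training
recipe. Missing keys fall back to the calibrated defaults, so an empty
mapping is a valid config.

Schema (all sections optional)::

    arch:
      num_classes: 8
      repeats: [1, 1, 2, 3, 1, 4, 1]     # must sum to total_mbconv_blocks
      total_mbconv_blocks: 13
    eca: {kernel_sizes: [3, 5, 7], fusion: mean}
    ccm: {reduction: 16}
    aspp: {rates: [3, 6, 9], branch_channels: 94, gap_channels: 128}
    head: {lambda_init: 0.5, retain_1x1_expand: true, dropout_rate: 0.2}
    droppath: {p_max: 0.2}
    train:
      epochs: 200
      batch_size: 32
      lr_max: 1.0e-3
      lr_min: 0.0
      label_smoothing_eps: 0.1
      seed: 0
"""

from __future__ import annotations

import yaml

from .blocks import BlockConfig
from .network import _B0_STAGES, ArchitectureConfig, HeadConfig, StageSpec
from .training import TrainConfig

__all__ = [
    "load_config",
    "save_config",
    "architecture_from_config",
    "train_config_from_config",
    "config_from_architecture",
]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def architecture_from_config(cfg: dict) -> ArchitectureConfig:
    default = ArchitectureConfig.enet_caem_default()
    arch = cfg.get("arch", {})
    eca = cfg.get("eca", {})
    ccm = cfg.get("ccm", {})
    aspp = cfg.get("aspp", {})
    head = cfg.get("head", {})
    droppath = cfg.get("droppath", {})

    block = BlockConfig(
        eca_kernel_sizes=tuple(eca.get("kernel_sizes", default.block.eca_kernel_sizes)),
        eca_fusion=eca.get("fusion", default.block.eca_fusion),
        ccm_reduction=int(ccm.get("reduction", default.block.ccm_reduction)),
        aspp_rates=tuple(aspp.get("rates", default.block.aspp_rates)),
        aspp_branch_channels=int(
            aspp.get("branch_channels", default.block.aspp_branch_channels)
        ),
        aspp_gap_channels=int(aspp.get("gap_channels", default.block.aspp_gap_channels)),
        mixed_pool_lambda_init=float(
            head.get("lambda_init", default.block.mixed_pool_lambda_init)
        ),
        droppath_p_max=float(droppath.get("p_max", default.block.droppath_p_max)),
    )
    repeats = arch.get("repeats")
    stages = []
    for i, (e, k, s, c, _) in enumerate(_B0_STAGES):
        r = repeats[i] if repeats else default.stages[i].repeats
        stages.append(StageSpec(e, k, s, c, int(r), use_ccm=c in (40, 80, 112)))
    return ArchitectureConfig(
        stages=stages,
        num_classes=int(arch.get("num_classes", 8)),
        input_size=tuple(arch.get("input_size", (224, 224))),
        head=HeadConfig(
            retain_1x1_expand=bool(
                head.get("retain_1x1_expand", default.head.retain_1x1_expand)
            ),
            dropout_rate=float(head.get("dropout_rate", default.head.dropout_rate)),
        ),
        block=block,
        total_mbconv_blocks=int(
            arch.get("total_mbconv_blocks", sum(s.repeats for s in stages))
        ),
    )


def train_config_from_config(cfg: dict) -> TrainConfig:
    t = cfg.get("train", {})
    return TrainConfig(
        epochs=int(t.get("epochs", 200)),
        batch_size=int(t.get("batch_size", 32)),
        lr_max=float(t.get("lr_max", 1e-3)),
        lr_min=float(t.get("lr_min", 0.0)),
        label_smoothing_eps=float(t.get("label_smoothing_eps", 0.1)),
        weight_decay=float(t.get("weight_decay", 0.0)),
        seed=int(t.get("seed", 0)),
    )


def config_from_architecture(arch: ArchitectureConfig, train: TrainConfig | None = None) -> dict:
    b = arch.block
    cfg = {
        "arch": {
            "num_classes": arch.num_classes,
            "repeats": [s.repeats for s in arch.stages],
            "total_mbconv_blocks": arch.total_mbconv_blocks,
            "input_size": list(arch.input_size),
        },
        "eca": {"kernel_sizes": list(b.eca_kernel_sizes), "fusion": b.eca_fusion},
        "ccm": {"reduction": b.ccm_reduction},
        "aspp": {
            "rates": list(b.aspp_rates),
            "branch_channels": b.aspp_branch_channels,
            "gap_channels": b.aspp_gap_channels,
        },
        "head": {
            "lambda_init": b.mixed_pool_lambda_init,
            "retain_1x1_expand": arch.head.retain_1x1_expand,
            "dropout_rate": arch.head.dropout_rate,
        },
        "droppath": {"p_max": b.droppath_p_max},
    }
    if train is not None:
        cfg["train"] = {
            "epochs": train.epochs,
            "batch_size": train.batch_size,
            "lr_max": train.lr_max,
            "lr_min": train.lr_min,
            "label_smoothing_eps": train.label_smoothing_eps,
            "seed": train.seed,
        }
    return cfg
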