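"""Training recipe: Adam, cosine-annealed learning rate, label-smoothed
cross-entropy, per-epoch validation, best-checkpoint retention.

Defaults follow the published recipe — 200 epochs, batch 32,
Adam(beta1=0.9, beta2=0.999) — with the unstated pieces fixed as:
lr_max = 1e-3 annealed to lr_min = 0, smoothing eps = 0.1 with the
uniform-mixture convention q = (1 - eps) * onehot + eps / K, no weight
decay, no early stopping. Runs are bit-reproducible given the config
seed, which drives data order, dropout and drop-path draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .blocks import LearnableDropPath, MixedPool
from .datapipe import LabeledDataset

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cosine_lr",
    "label_smoothing_ce",
    "preprocess",
    "train",
    "predict",
]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    lr_max: float = 1e-3
    lr_min: float = 0.0
    label_smoothing_eps: float = 0.1
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.lr_min < 0 or self.lr_min > self.lr_max:
            raise ValueError("need 0 <= lr_min <= lr_max")
        if not 0.0 <= self.label_smoothing_eps < 1.0:
            raise ValueError("label smoothing eps must lie in [0, 1)")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    mixed_pool_lambda: list = field(default_factory=list)
    drop_probs: list = field(default_factory=list)

    def to_rows(self) -> list:
        return [
            {
                "epoch": e,
                "train_loss": tl,
                "val_loss": vl,
                "val_accuracy": va,
                "lr": lr,
                "mixed_pool_lambda": lam,
            }
            for e, tl, vl, va, lr, lam in zip(
                self.epoch,
                self.train_loss,
                self.val_loss,
                self.val_accuracy,
                self.lr,
                self.mixed_pool_lambda,
            )
        ]


def cosine_lr(t: int, T: int, lr_max: float, lr_min: float = 0.0) -> float:
    """lr(t) = lr_min + (lr_max - lr_min) * (1 + cos(pi t / T)) / 2."""
    if T < 1:
        raise ValueError("total epochs must be >= 1")
    if not 0 <= t <= T:
        raise ValueError("epoch index out of range")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / T))


def label_smoothing_ce(logits: Tensor, labels: np.ndarray, eps: float = 0.0) -> Tensor:
    """Cross-entropy against q = (1 - eps) * onehot + eps / K, batch mean."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    B, K = logits.shape
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("label outside [0, K)")
    q = np.full((B, K), eps / K, dtype=np.float32)
    q[np.arange(B), labels] += 1.0 - eps
    logp = nn.log_softmax(logits, axis=1)
    return -(logp * Tensor(q)).sum(axis=1).mean()


def preprocess(ds: LabeledDataset) -> tuple:
    """uint8 H x W x 3 images -> float32 B x 3 x H x W in [-1, 1]."""
    x = ds.images().astype(np.float32).transpose(0, 3, 1, 2)
    return (x / 255.0 - 0.5) / 0.5, ds.labels()


def predict(net: nn.Module, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Argmax predictions in eval mode."""
    was_training = net.training
    net.eval()
    preds = []
    for i in range(0, len(x), batch_size):
        out = net(Tensor(x[i : i + batch_size]))
        preds.append(out.data.argmax(axis=1))
    if was_training:
        net.train()
    return np.concatenate(preds)


def _monitor(net: nn.Module) -> tuple:
    lam = None
    drops = []
    for m in net.modules():
        if isinstance(m, MixedPool):
            lam = m.lam
        elif isinstance(m, LearnableDropPath):
            drops.append(m.p)
    return lam, drops


def train(
    net: nn.Module,
    train_ds: LabeledDataset,
    val_ds: LabeledDataset,
    cfg: TrainConfig | None = None,
) -> tuple:
    """Train ``net``; returns (best_state_dict, TrainHistory).

    The best checkpoint is the epoch with the highest validation accuracy
    (ties resolved toward the earlier epoch). A non-finite loss aborts
    with a diagnostic naming the epoch and batch.
    """
    cfg = cfg or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("datasets must be non-empty")
    K = train_ds.num_classes
    fc = getattr(net, "fc", None)
    if fc is not None and fc.out_features != K:
        raise ValueError(f"network has {fc.out_features} outputs but data has {K} classes")

    xtr, ytr = preprocess(train_ds)
    xval, yval = preprocess(val_ds)
    rng = np.random.default_rng(cfg.seed)
    if hasattr(net, "seed_stochastic"):
        net.seed_stochastic(cfg.seed + 1)
    opt = nn.Adam(net.parameters(), lr=cfg.lr_max, weight_decay=cfg.weight_decay)
    hist = TrainHistory()
    best_acc, best_state = -1.0, None

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr_max, cfg.lr_min)
        opt.lr = lr
        net.train()
        order = rng.permutation(len(xtr))
        losses = []
        for bi, i in enumerate(range(0, len(order), cfg.batch_size)):
            idx = order[i : i + cfg.batch_size]
            logits = net(Tensor(xtr[idx]))
            loss = label_smoothing_ce(logits, ytr[idx], cfg.label_smoothing_eps)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        net.eval()
        val_logits = []
        for i in range(0, len(xval), cfg.batch_size):
            val_logits.append(net(Tensor(xval[i : i + cfg.batch_size])).data)
        val_logits = np.concatenate(val_logits)
        val_loss = float(
            label_smoothing_ce(Tensor(val_logits), yval, cfg.label_smoothing_eps).data
        )
        val_acc = float((val_logits.argmax(axis=1) == yval).mean())

        lam, drops = _monitor(net)
        hist.epoch.append(epoch)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        hist.lr.append(lr)
        hist.mixed_pool_lambda.append(lam)
        hist.drop_probs.append(drops)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = {k: v.copy() for k, v in net.state_dict().items()}

    return best_state, hist
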