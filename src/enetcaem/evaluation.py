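"""Evaluation: confusion matrices, accuracy / precision / recall / F1,
and stratified k-fold cross-validation.

Per-class metrics follow the one-vs-rest convention: for class k,
precision = TP / (TP + FP), recall = TP / (TP + FN), F1 is their harmonic
mean; aggregates are macro (unweighted class means) by default, with
micro averaging available. A zero denominator yields 0 and raises a flag
rather than NaN. Cross-validation reports per-fold metrics and the
mean +/- sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datapipe import LabeledDataset

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "cross_validate",
    "kfold_cv",
    "summarize_folds",
]


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    undefined: list = field(default_factory=list)  # (class, metric) pairs set to 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "confusion_matrix": self.confusion.tolist(),
            "undefined": self.undefined,
        }


def confusion_matrix(preds, labels, num_classes: int) -> np.ndarray:
    """counts[i, j] = number of samples with true class i predicted as j."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if len(preds) and (
        preds.min() < 0 or preds.max() >= num_classes or labels.min() < 0 or labels.max() >= num_classes
    ):
        raise ValueError("class index outside [0, K)")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def compute_metrics(cm: np.ndarray, average: str = "macro") -> MetricsReport:
    """Metrics from a confusion matrix (rows true, columns predicted)."""
    cm = np.asarray(cm)
    K = cm.shape[0]
    total = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    undefined = []

    def safe_div(num, den, metric):
        out = np.zeros(K)
        for k in range(K):
            if den[k] == 0:
                undefined.append((k, metric))
            else:
                out[k] = num[k] / den[k]
        return out

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    for k in range(K):
        if pr[k] == 0:
            undefined.append((k, "f1"))
    accuracy = float(tp.sum() / total) if total else 0.0
    if average == "macro":
        mp, mr, mf = precision.mean(), recall.mean(), f1.mean()
    elif average == "micro":
        denom = tp.sum() + fp.sum()
        mp = mr = float(tp.sum() / denom) if denom else 0.0
        mf = mp  # micro precision = recall = F1 in single-label classification
    else:
        raise ValueError("average must be 'macro' or 'micro'")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(mp),
        macro_recall=float(mr),
        macro_f1=float(mf),
        confusion=cm,
        undefined=undefined,
    )


def _check_fold_sizes(labels: np.ndarray, k: int):
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} items; need >= k = {k}")


def cross_validate(ds: LabeledDataset, k: int, fit_predict, seed: int = 0) -> list:
    """Generic stratified k-fold loop.

    ``fit_predict(train_ds, test_ds) -> predictions`` is called once per
    fold; returns one MetricsReport per fold. Fold assignment is
    deterministic given the seed, holdouts are disjoint and cover the
    dataset.
    """
    labels = ds.labels()
    _check_fold_sizes(labels, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        train_part, test_part = ds.subset(train_idx), ds.subset(test_idx)
        preds = fit_predict(train_part, test_part)
        cm = confusion_matrix(preds, test_part.labels(), ds.num_classes)
        reports.append(compute_metrics(cm))
    return reports


def kfold_cv(
    ds: LabeledDataset,
    k: int = 5,
    traincfg=None,
    archcfg=None,
    seed: int = 0,
) -> tuple:
    """Train the network from scratch on each fold; returns (reports, summary)."""
    from .network import ArchitectureConfig, build_enet_caem
    from .training import TrainConfig, predict, preprocess, train

    traincfg = traincfg or TrainConfig()
    archcfg = archcfg or ArchitectureConfig.enet_caem_default(num_classes=ds.num_classes)

    def fit_predict(train_part, test_part):
        net = build_enet_caem(archcfg, seed=traincfg.seed)
        best_state, _ = train(net, train_part, test_part, traincfg)
        net.load_state_dict(best_state)
        x, _ = preprocess(test_part)
        return predict(net, x, traincfg.batch_size)

    reports = cross_validate(ds, k, fit_predict, seed=seed)
    return reports, summarize_folds(reports)


def summarize_folds(reports: list) -> dict:
    """Per-metric mean and sample standard deviation, 'mean+/-std' formatted."""
    out = {}
    for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        vals = np.array([getattr(r, name) for r in reports])
        mean = float(vals.mean())
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = {
            "mean": mean,
            "std": std,
            "formatted": f"{100 * mean:.2f}+/-{100 * std:.2f}",
        }
    return out
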