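"""Metrics and cross-validation on predictions.

Builds a confusion matrix from predictions, derives accuracy and
per-class precision/recall/F1 (macro-averaged), and runs the stratified
k-fold loop with a stand-in classifier to show the fold bookkeeping
without a long training run.
"""

import numpy as np

from enetcaem.evaluation import compute_metrics, confusion_matrix, cross_validate, summarize_folds
from enetcaem.synthetic import SynthSpec, generate_dataset

# metrics from a hand-made prediction vector
labels = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
preds = np.array([0, 0, 1, 1, 1, 2, 2, 0, 2])
cm = confusion_matrix(preds, labels, 3)
rep = compute_metrics(cm)
print("confusion matrix (rows = true, cols = predicted):")
print(cm)
print(f"accuracy {rep.accuracy:.3f}  macro-P {rep.macro_precision:.3f}  "
      f"macro-R {rep.macro_recall:.3f}  macro-F1 {rep.macro_f1:.3f}")

# stratified 5-fold loop with a colour-mean stand-in classifier
ds = generate_dataset(SynthSpec(n_per_class=15, image_size=32, seed=0))


def nearest_mean_fit_predict(train_part, test_part):
    feats = lambda part: np.stack([img.reshape(-1, 3).mean(0) for img, _ in part.items])
    Xtr, ytr = feats(train_part), train_part.labels()
    cents = np.stack([Xtr[ytr == k].mean(0) for k in range(train_part.num_classes)])
    Xte = feats(test_part)
    return np.argmin(((Xte[:, None] - cents[None]) ** 2).sum(-1), axis=1)


reports = cross_validate(ds, 5, nearest_mean_fit_predict, seed=0)
summary = summarize_folds(reports)
print("\n5-fold CV with a nearest-mean-colour classifier:")
for i, r in enumerate(reports):
    print(f"  fold {i + 1}: accuracy {r.accuracy:.3f}")
print(f"  accuracy {summary['accuracy']['formatted']} (mean +/- sample std, percent)")
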