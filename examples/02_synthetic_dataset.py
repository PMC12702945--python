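"""Generate a synthetic 8-class lesion dataset and check its separability.

Writes a small directory-per-class image tree and shows that, with noise
disabled, a leave-one-out nearest-neighbour classifier on joint RGB
colour histograms separates the eight classes perfectly — the guarantee
that makes the set a meaningful training target.
"""

import numpy as np

from enetcaem.datapipe import save_image_folder
from enetcaem.synthetic import SynthSpec, generate_dataset

ds = generate_dataset(SynthSpec(n_per_class=8, image_size=64, noise_sigma=0.0, seed=0))
save_image_folder(ds, "scratch/synthetic_demo")
print(f"wrote {len(ds)} images ({ds.num_classes} classes) to scratch/synthetic_demo/")


def joint_hist(img, bins=4):
    q = (img.astype(np.int32) * bins) >> 8
    idx = (q[..., 0] * bins + q[..., 1]) * bins + q[..., 2]
    h = np.bincount(idx.ravel(), minlength=bins**3).astype(float)
    return h / h.sum()


X = np.stack([joint_hist(img) for img, _ in ds.items])
y = ds.labels()
D = np.abs(X[:, None, :] - X[None]).sum(-1)
np.fill_diagonal(D, np.inf)
acc = (y[np.argmin(D, axis=1)] == y).mean()
print(f"leave-one-out colour-histogram 1-NN accuracy: {acc:.3f}")
print("(1.000 means every class is identifiable from colour content alone)")
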