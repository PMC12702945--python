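"""Run the data pipeline: augment, balance, stratified 8:1:1 split.

Each source image yields two augmented versions (2-3 transforms sampled
from rotation/flip/crop/blur/noise/colour jitter), classes are resampled
to the median class size, and the result is split with per-class
largest-remainder rounding so the three parts partition every class.
"""

from enetcaem.datapipe import augment_dataset, balance_classes, stratified_split
from enetcaem.synthetic import SynthSpec, generate_dataset

ds = generate_dataset(SynthSpec(n_per_class=6, image_size=224, seed=1))
print(f"original: {len(ds)} images, per-class counts {list(ds.class_counts().values())}")

aug = augment_dataset(ds, seed=1)
print(f"after augmentation (2 versions/image): {len(aug)} images")

bal = balance_classes(aug, {k: 16 for k in range(8)}, seed=1)
print(f"after balancing to 16/class: {len(bal)} images")

train, val, test = stratified_split(bal, (0.8, 0.1, 0.1), seed=1)
print(f"split 8:1:1 -> train {len(train)}, val {len(val)}, test {len(test)}")
print(f"train per-class: {list(train.class_counts().values())}")
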