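"""Dataset plumbing: augmentation, class balancing, stratified splitting,
and directory-per-class image I/O.

The augmentation policy mirrors a field-photography protocol for leaf and
fruit disease images: random rotation in [-45, 45] degrees, horizontal
flip, random 200x200 crop resized back to 224x224, Gaussian blur with
radius in [0.5, 1.5], additive Gaussian noise with sigma = 10 intensity
units, and brightness / contrast / saturation jitter. Each augmentation
cycle samples a combination of 2-3 transforms (without replacement) and
produces two augmented versions per source image.

Class imbalance is handled by resampling (with replacement up, without
replacement down) to explicit per-class targets, and datasets are split
8:1:1 with per-class largest-remainder rounding. Every operation is a
pure function of (input, seed).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageEnhance, ImageFilter
from sklearn.utils import resample

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationPolicy",
    "LabeledDataset",
    "augment_image",
    "augment_dataset",
    "balance_classes",
    "stratified_split",
    "load_image_folder",
    "save_image_folder",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class AugmentationPolicy:
    """Parameter ranges of the augmentation transforms."""

    rotation_deg: tuple = (-45.0, 45.0)
    hflip_prob: float = 0.5
    crop_size: int = 200
    output_size: int = 224
    blur_radius: tuple = (0.5, 1.5)
    noise_sigma: float = 10.0
    brightness: tuple = (0.7, 1.3)
    contrast: tuple = (0.8, 1.2)
    saturation: tuple = (0.6, 1.4)
    transforms_per_image: tuple = (2, 3)
    versions_per_image: int = 2

    TRANSFORM_NAMES = (
        "rotation",
        "hflip",
        "crop",
        "blur",
        "noise",
        "brightness",
        "contrast",
        "saturation",
    )


@dataclass
class LabeledDataset:
    """Images (H x W x 3 uint8 RGB) with integer labels and class names."""

    items: list = field(default_factory=list)  # list of (image, label)
    class_names: list = field(default_factory=list)

    def __len__(self):
        return len(self.items)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=np.int64)

    def images(self) -> np.ndarray:
        return np.stack([img for img, _ in self.items])

    def class_counts(self) -> dict:
        counts = dict.fromkeys(range(self.num_classes), 0)
        for _, lab in self.items:
            counts[lab] += 1
        return counts

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in indices], list(self.class_names))


def _to_pil(img) -> Image.Image:
    if isinstance(img, Image.Image):
        return img.convert("RGB")
    return Image.fromarray(np.asarray(img, dtype=np.uint8), "RGB")


def _apply_transform(
    img: Image.Image, name: str, policy: AugmentationPolicy, rng: np.random.Generator
) -> Image.Image:
    if name == "rotation":
        angle = rng.uniform(*policy.rotation_deg)
        return img.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    if name == "hflip":
        return img.transpose(Image.FLIP_LEFT_RIGHT)
    if name == "crop":
        c = policy.crop_size
        x0 = int(rng.integers(0, img.width - c + 1))
        y0 = int(rng.integers(0, img.height - c + 1))
        out = policy.output_size
        return img.crop((x0, y0, x0 + c, y0 + c)).resize((out, out), Image.BILINEAR)
    if name == "blur":
        return img.filter(ImageFilter.GaussianBlur(rng.uniform(*policy.blur_radius)))
    if name == "noise":
        arr = np.asarray(img, dtype=np.float32)
        noisy = arr + rng.normal(0.0, policy.noise_sigma, size=arr.shape)
        return Image.fromarray(np.clip(noisy, 0, 255).astype(np.uint8), "RGB")
    if name == "brightness":
        return ImageEnhance.Brightness(img).enhance(rng.uniform(*policy.brightness))
    if name == "contrast":
        return ImageEnhance.Contrast(img).enhance(rng.uniform(*policy.contrast))
    if name == "saturation":
        return ImageEnhance.Color(img).enhance(rng.uniform(*policy.saturation))
    raise ValueError(f"unknown transform {name!r}")


def augment_image(img, policy: AugmentationPolicy | None = None, seed: int = 0) -> list:
    """Produce ``versions_per_image`` augmented 224x224 copies of one image.

    Each version applies an independently sampled combination of 2-3
    transforms (drawn without replacement); deterministic given ``seed``.
    Returns a list of H x W x 3 uint8 arrays.
    """
    policy = policy or AugmentationPolicy()
    pil = _to_pil(img)
    out_size = policy.output_size
    if pil.width < policy.crop_size or pil.height < policy.crop_size:
        raise ValueError(
            f"image of size {pil.size} is smaller than the {policy.crop_size} crop window"
        )
    rng = np.random.default_rng(seed)
    versions = []
    for _ in range(policy.versions_per_image):
        n = int(rng.integers(policy.transforms_per_image[0], policy.transforms_per_image[1] + 1))
        chosen = rng.choice(len(policy.TRANSFORM_NAMES), size=n, replace=False)
        v = pil
        for t in chosen:
            v = _apply_transform(v, policy.TRANSFORM_NAMES[t], policy, rng)
        if v.size != (out_size, out_size):
            v = v.resize((out_size, out_size), Image.BILINEAR)
        versions.append(np.asarray(v.convert("RGB"), dtype=np.uint8))
    return versions


def augment_dataset(
    ds: LabeledDataset, policy: AugmentationPolicy | None = None, seed: int = 0
) -> LabeledDataset:
    """Originals plus their augmented versions, labels preserved."""
    policy = policy or AugmentationPolicy()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(ds))
    items = []
    for (img, lab), s in zip(ds.items, seeds):
        items.append((np.asarray(_to_pil(img)), lab))
        for aug in augment_image(img, policy, int(s)):
            items.append((aug, lab))
    return LabeledDataset(items, list(ds.class_names))


def balance_classes(
    ds: LabeledDataset, target_counts: dict | None = None, seed: int = 0
) -> LabeledDataset:
    """Resample each class to its target size.

    Classes below target are sampled with replacement (oversampling);
    classes above target are sampled without replacement (downsampling).
    Default targets: the median class size, applied to every class.
    """
    counts = ds.class_counts()
    if target_counts is None:
        med = int(np.median([c for c in counts.values() if c > 0]))
        target_counts = {k: med for k in counts}
    rng_state = np.random.RandomState(seed)  # sklearn resample wants legacy state
    items = []
    for cls in range(ds.num_classes):
        target = int(target_counts.get(cls, counts[cls]))
        if target <= 0:
            raise ValueError(f"target count for class {cls} must be positive")
        members = [it for it in ds.items if it[1] == cls]
        if not members:
            raise ValueError(f"class {cls} is empty but has a positive target")
        if len(members) == target:
            chosen = members
        else:
            chosen = resample(
                members,
                replace=len(members) < target,
                n_samples=target,
                random_state=rng_state,
            )
        items.extend(chosen)
    return LabeledDataset(items, list(ds.class_names))


def _largest_remainder(n: int, ratios) -> list:
    """Integer partition of n proportional to ratios, summing exactly to n."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for i in range(short):
        base[order[i]] += 1
    return base


def stratified_split(
    ds: LabeledDataset, ratios: tuple = (0.8, 0.1, 0.1), seed: int = 0
) -> tuple:
    """Split into (train, val, test) preserving per-class proportions.

    Per class, counts follow largest-remainder rounding of the ratios, so
    the three parts always partition the class exactly.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    parts = [[], [], []]
    labels = ds.labels()
    for cls in range(ds.num_classes):
        idx = np.flatnonzero(labels == cls)
        if len(idx) and len(idx) < 3:
            raise ValueError(f"class {cls} has {len(idx)} items; need >= 3 to split")
        rng.shuffle(idx)
        sizes = _largest_remainder(len(idx), ratios)
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].extend(idx[:a])
        parts[1].extend(idx[a:b])
        parts[2].extend(idx[b:])
    return tuple(ds.subset(sorted(p)) for p in parts)


def load_image_folder(root) -> LabeledDataset:
    """Read a directory-per-class tree; class order is lexicographic."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class directories")
    items = []
    names = []
    for label, d in enumerate(class_dirs):
        names.append(d.name)
        files = sorted(d.iterdir())
        images = 0
        for f in files:
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                if f.is_file():
                    logger.warning("skipping non-image file %s", f)
                continue
            try:
                img = Image.open(f).convert("RGB")
            except OSError as e:
                raise ValueError(f"unreadable image file {f}: {e}") from e
            items.append((np.asarray(img, dtype=np.uint8), label))
            images += 1
        if images == 0:
            raise ValueError(f"class directory {d} contains no images")
    return LabeledDataset(items, names)


def save_image_folder(ds: LabeledDataset, root, manifest: bool = True):
    """Write the directory-per-class layout (PNG) plus a manifest CSV."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = dict.fromkeys(range(ds.num_classes), 0)
    for img, lab in ds.items:
        d = root / ds.class_names[lab]
        d.mkdir(exist_ok=True)
        path = d / f"{ds.class_names[lab]}_{counters[lab]:05d}.png"
        Image.fromarray(img, "RGB").save(path)
        rows.append((str(path.relative_to(root)), lab))
        counters[lab] += 1
    if manifest:
        with open(root / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filepath", "label", "class_name"])
            for p, lab in rows:
                w.writerow([p, lab, ds.class_names[lab]])
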