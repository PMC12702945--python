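import numpy as np
import pytest

from enetcaem.datapipe import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_dataset(counts, image_size=8, num_classes=None, seed=0):
    """A LabeledDataset of tiny random images with the given class counts."""
    num_classes = num_classes or len(counts)
    g = np.random.default_rng(seed)
    items = []
    for cls, n in counts.items():
        for _ in range(n):
            img = g.integers(0, 256, size=(image_size, image_size, 3), dtype=np.uint8)
            items.append((img, cls))
    names = [f"class_{k}" for k in range(num_classes)]
    return LabeledDataset(items, names)


@pytest.fixture
def toy_dataset():
    return make_toy_dataset({k: 10 for k in range(4)})
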