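import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, h, w, p=0.3):
    return rng.random((h, w)) < p


@pytest.fixture
def mask_pairs(rng):
    """Random binary mask pairs of 16-32 px used by the metric oracle tests."""
    pairs = []
    while len(pairs) < 200:
        h = int(rng.integers(16, 33))
        w = int(rng.integers(16, 33))
        gt = random_mask(rng, h, w, float(rng.uniform(0.1, 0.5)))
        seg = random_mask(rng, h, w, float(rng.uniform(0.1, 0.5)))
        pairs.append((gt, seg))
    return pairs
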