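import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_label_mask(rng, shape=(32, 32), max_instances=10):
    """Random blobby label mask: a few disk-ish instances on a grid."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(1, max_instances + 1))
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(1, n + 1):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(2, 6)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[mask] = k  # later instances may overwrite earlier ones
    return labels


def random_binary_mask(rng, shape=(32, 32), p=0.3):
    return rng.random(shape) < p
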