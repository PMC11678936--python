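import numpy as np
import pytest

from headseg.metrics import InstanceMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape=(24, 24), n_seeds=3, radius=(2, 6)):
    """Random non-empty union-of-discs mask (small, for brute-force oracles)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        cy, cx = rng.uniform(2, h - 2), rng.uniform(2, w - 2)
        r = rng.uniform(*radius)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask


def square_mask(shape, y1, x1, y2, x2):
    m = np.zeros(shape, dtype=bool)
    m[y1:y2, x1:x2] = True
    return m


def inst(mask, conf=None, class_id=0):
    return InstanceMask(mask=mask, confidence=conf, class_id=class_id)


@pytest.fixture
def blob_pair_factory(rng):
    def make():
        return random_blob_mask(rng), random_blob_mask(rng)

    return make
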