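import dataclasses

import numpy as np
import pytest

from dhunet.config import SyntheticSpec
from dhunet.synthetic import generate_sample, sample_seed


def make_array_dataset(seed: int, n: int, size: int):
    """Materialise n synthetic samples as (X, Y) network-ready arrays."""
    xs, ys = [], []
    template = SyntheticSpec(seed=seed, size=size)
    for i in range(n):
        spec = dataclasses.replace(template, seed=sample_seed(seed, i))
        img, msk = generate_sample(spec)
        xs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(msk)
    return np.stack(xs), np.stack(ys)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 samples at 32 px, shared by fast training tests."""
    return make_array_dataset(seed=5, n=12, size=32)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
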