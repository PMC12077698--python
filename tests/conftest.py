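import numpy as np
import pytest

from vmdecg.datasets import make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small but structurally complete dataset (3 classes, split, noise)."""
    return make_dataset(n_points=10, n_replicates=2, seed=11)


@pytest.fixture(scope="session")
def model0_record(small_dataset):
    ds = small_dataset
    idx = next(i for i, s in enumerate(ds.signals) if s.label == "model0")
    return ds.signals[idx]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
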