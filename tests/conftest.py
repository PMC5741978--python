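import numpy as np
import pytest

from ksrmkl import data_io, features, synthetic
from ksrmkl.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def strong_data():
    """Default strong-signal synthetic dataset (seed 0)."""
    return synthetic.generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def strong_dataset(strong_data):
    return data_io.build_kinase_dataset(strong_data.sites, "KIN_A", 25)


@pytest.fixture(scope="session")
def strong_views(strong_data, strong_dataset):
    return features.build_feature_views(
        strong_dataset, strong_data.sequences, strong_data.ppi
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_psd(rng, n, rank=None):
    """Random PSD matrix (a Gram matrix of random vectors)."""
    A = rng.normal(size=(n, rank or n))
    return A @ A.T


def random_labels(rng, n):
    """Label vector guaranteed to contain both classes."""
    while True:
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) == 2:
            return y
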