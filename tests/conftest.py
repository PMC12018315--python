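import numpy as np
import pytest

from qsaropt.datasets import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One desk-scale synthetic dataset shared by read-only tests."""
    cfg = GeneratorConfig(n_train=300, n_test=50, n_descriptors=120, n_zero_cols=37,
                          n_signal=8, n_collinear_pairs=5, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
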