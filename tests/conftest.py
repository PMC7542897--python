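import numpy as np
import pytest

from robustelm import SyntheticSpec, gaussian_classes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """Random (H, T) pair with N > L, two target columns."""
    N, L, M = 10, 4, 2
    H = rng.uniform(0.05, 0.95, size=(N, L))
    T = np.zeros((N, M))
    T[np.arange(N), rng.integers(0, M, N)] = 1.0
    return H, T


@pytest.fixture
def gaussian_dataset():
    """The default two-class planar benchmark (300 per class, no noise)."""
    return gaussian_classes(SyntheticSpec(seed=0))
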