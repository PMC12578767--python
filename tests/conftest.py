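import numpy as np
import pytest
from hypothesis import settings

from tropgrad import treespace

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def branching_6x10():
    """Normalized cophenetic dataset of 10 branching trees on 4 leaves."""
    trees = [
        treespace.sample_tree("branching", 4, np.random.default_rng(100 + i))
        for i in range(10)
    ]
    return treespace.normalize_avg_norm(treespace.tree_data_matrix(trees))


@pytest.fixture(scope="session")
def coalescent_6x10():
    """Normalized cophenetic dataset of 10 coalescent trees on 4 leaves."""
    trees = [
        treespace.sample_tree("coalescent", 4, np.random.default_rng(300 + i))
        for i in range(10)
    ]
    return treespace.normalize_avg_norm(treespace.tree_data_matrix(trees))
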