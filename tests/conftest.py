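import numpy as np
import pytest

from treevae.trees import enumerate_topologies


def labels(n):
    return [f"t{i}" for i in range(1, n + 1)]


@pytest.fixture(scope="session")
def five_leaf_labels():
    return labels(5)


@pytest.fixture(scope="session")
def five_leaf_space(five_leaf_labels):
    return enumerate_topologies(five_leaf_labels)


@pytest.fixture(scope="session")
def six_leaf_space():
    return enumerate_topologies(labels(6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
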