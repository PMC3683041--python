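import numpy as np
import pytest

from diprog.scoring import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20130614)


def random_binary_data(rng, m, n, p=0.5, names=None) -> DataMatrix:
    return DataMatrix((rng.random((m, n)) < p).astype(int), names)


@pytest.fixture
def coin_data(rng):
    """Two independent fair coins, m=400."""
    return random_binary_data(rng, 400, 2, names=["A", "B"])
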