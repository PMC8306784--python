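import numpy as np
import pytest

from aifcollective import WorldConfig


@pytest.fixture
def cfg():
    """Default 60-cell world, field centred on the shared target."""
    return WorldConfig()


@pytest.fixture
def cfg7():
    """Tiny 7-cell world for brute-force comparisons."""
    return WorldConfig(n_cells=7, center=3, targets={"shared": 3, "a": 1, "b": 5}, omega=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_belief(rng, n, sharp=False):
    """Random canonical log-belief vector in [-10, 0] with max 0."""
    if sharp:
        b = rng.uniform(-10.0, 0.0, n)
        b[rng.integers(n)] = 0.0
    else:
        b = rng.uniform(-6.0, 0.0, n)
    return np.maximum(b - b.max(), -10.0)
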