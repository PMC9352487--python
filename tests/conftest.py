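import numpy as np
import pytest

from greypsy.indices import IndexDefinition, IndexSystem, default_index_system


@pytest.fixture(scope="session")
def system():
    return default_index_system()


@pytest.fixture
def small_system():
    """Three-index system with weights (0.2, 0.3, 0.5)."""
    return IndexSystem((
        IndexDefinition("a", 20, (4, 8, 12, 16)),
        IndexDefinition("b", 30, (6, 12, 18, 24)),
        IndexDefinition("c", 50, (10, 20, 30, 40)),
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
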