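import numpy as np
import pytest

from antjump import FiberSet, PhysiologicalConstants


@pytest.fixture
def constants():
    return PhysiologicalConstants()


@pytest.fixture
def simple_fibers():
    """Three parallel fibers of lengths 1, 2, 3 m (mean 2 m)."""
    return FiberSet([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
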