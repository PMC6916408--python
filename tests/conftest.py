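import numpy as np
import pytest

from mosaicbrain.trees import read_tree


@pytest.fixture
def three_tip_tree():
    """Ultrametric 3-tip tree: ((A:1,B:1):1,C:2)."""
    return read_tree("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def cherry():
    return read_tree("(A:1,B:1):0;")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
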