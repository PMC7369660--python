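import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_row():
    """1x6 quantized row whose run structure is enumerable by hand."""
    return np.array([[1, 1, 2, 2, 2, 3]])


@pytest.fixture
def toy_levels_3x3():
    """3x3 two-level image with 6 horizontal ordered pairs."""
    return np.array([[1, 1, 2], [1, 2, 2], [2, 2, 2]])
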