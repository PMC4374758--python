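import numpy as np
import pytest

from mixedica.core import ModelCategory, center_rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """A well-conditioned 3 x 40 centered observation matrix."""
    return center_rows(rng.standard_normal((3, 40)))


@pytest.fixture
def mixed_category():
    return ModelCategory(1, 1, 1)
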