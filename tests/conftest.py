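import numpy as np
import pytest

from lumispark.phantom import make_embryo_phantom


@pytest.fixture
def phantom():
    """Default full-size embryo phantom (10 somites, 128×128 binned px)."""
    return make_embryo_phantom()


@pytest.fixture
def small_phantom():
    """Compact phantom for fast rendering tests."""
    return make_embryo_phantom(n_somites=6, somite_size=100.0,
                               image_shape=(64, 64), pixel_scale=12.8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
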