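import numpy as np
import pytest

from okcpipe import SyntheticSpec, generate_image


@pytest.fixture
def default_spec():
    return SyntheticSpec(seed=123)


@pytest.fixture
def okc_image(default_spec):
    return generate_image(default_spec)


@pytest.fixture
def nonokc_image():
    from okcpipe import NON_OKC

    return generate_image(SyntheticSpec(class_label=NON_OKC, seed=321))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_rgb(rng, h, w, low=0, high=256):
    """Small random RGB uint8 image."""
    return rng.integers(low, high, size=(h, w, 3), dtype=np.uint8)
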