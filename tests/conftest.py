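import numpy as np
import pytest

import randheads as rh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_image_set():
    """Separable 40-image synthetic set at toy-backbone working resolution."""
    spec = rh.SyntheticSpec(
        n_pos=30, n_neg=10, image_size=64, lesion_radius_range=(6, 12), seed=5
    )
    return rh.generate_images(spec)


@pytest.fixture(scope="session")
def toy_extractor(small_image_set):
    return rh.fine_tune(None, small_image_set, rh.FineTuneConfig(seed=5))
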