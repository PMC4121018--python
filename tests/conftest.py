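import numpy as np
import pytest

from woundbed.io import RgbImage
from woundbed.synthetic import WoundSpec, generate


@pytest.fixture(scope="session")
def small_wound():
    """One 96x96 synthetic wound with all three tissues present."""
    spec = WoundSpec(
        size=(96, 96),
        center=(48.0, 48.0),
        axes=(30.0, 22.0),
        rotation=0.5,
        fractions=(0.45, 0.40, 0.15),
        seed=17,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return RgbImage(rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8), id="rand")
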