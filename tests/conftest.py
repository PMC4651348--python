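import numpy as np
import pytest

from flockstudy.io import FixtureSpec, generate_image_fixtures
from flockstudy.stimulus_prep import StimulusImage


@pytest.fixture(scope="session")
def small_fixture_set():
    """A small seeded histology-like stimulus set (side 64) plus manifest."""
    return generate_image_fixtures(FixtureSpec(n_per_class=4, side=64, seed=11))


@pytest.fixture(scope="session")
def texture_308():
    """One display-resolution texture stimulus for compression tests."""
    images, _ = generate_image_fixtures(FixtureSpec(n_per_class=1, side=308, seed=7))
    return images[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_stimulus(rng, side=16, label="positive", sid="s0"):
    pixels = rng.integers(0, 256, size=(side, side, 3), dtype=np.uint8)
    return StimulusImage(id=sid, pixels=pixels, label=label)
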