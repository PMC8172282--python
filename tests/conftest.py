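import numpy as np
import pytest

from retina_frangi import (
    PhantomSpec,
    make_phantom,
    segment_detailed,
)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default seeded phantom without noise; known ground truth."""
    return make_phantom(PhantomSpec(seed=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def segmented_phantom(noise_free_phantom):
    """Full-pipeline segmentation of the noise-free phantom at defaults."""
    ph = noise_free_phantom
    return ph, segment_detailed(ph.rgb, ph.fov)


@pytest.fixture(scope="session")
def background_phantom():
    """Vessel-free phantom with mild noise."""
    return make_phantom(PhantomSpec(seed=1, vessel_count=0, noise_sigma=0.01))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
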