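import numpy as np
import pytest

from golgiseg import PhantomSpec, SegmentationParams, generate_phantom

#: Pipeline parameters documented for recovering the default phantom's tube.
PHANTOM_PIPELINE_PARAMS = SegmentationParams(
    max_stain_intensity=60,
    close_radius=4,
    blur_sigma=2.0,
    min_segment_intensity=40,
    min_segment_size=50,
    mask_only=True,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-spec phantom at the reference seed, shared across tests."""
    return generate_phantom(PhantomSpec(seed=20190115))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick phantom for I/O and CLI tests."""
    return generate_phantom(PhantomSpec(shape=(3, 96, 96), seed=7))


def random_mask(rng, shape=(32, 32), p=0.3):
    return rng.random(shape) < p
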