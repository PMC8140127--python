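import numpy as np
import pytest

from cmhseg import (BinaryMask, CalibratedImage, SyntheticSpec,
                    generate_image)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(16, 16), pixel_size_um=0.5, p=0.5):
    return BinaryMask(rng.random(shape) < p, pixel_size_um)


def random_image(rng, shape=(16, 16), pixel_size_um=0.5, high=256):
    px = rng.integers(0, high, size=shape + (3,), dtype=np.uint16)
    return CalibratedImage(px.astype(np.uint8 if high <= 256 else np.uint16),
                           pixel_size_um)


@pytest.fixture(scope="session")
def small_sample():
    """One small synthetic image with a shadow artifact, shared read-only."""
    spec = SyntheticSpec(image_shape=(160, 160), n_blobs=2,
                         blob_area_range_um2=(20.0, 400.0), n_shadows=1,
                         shadow_area_range_um2=(200.0, 800.0))
    return generate_image(spec, seed=7)
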