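import numpy as np
import pytest

import tsrzone
from tsrzone.core import TumorMask


@pytest.fixture(scope="session")
def phantom_default():
    """Noise-free phantom with dense inner band and sparse front band."""
    cfg = tsrzone.PhantomConfig(
        inner_target_fraction=0.9, front_target_fraction=0.3, noise_sd=0.0, seed=1
    )
    return tsrzone.generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom_noisy():
    cfg = tsrzone.PhantomConfig(
        inner_target_fraction=0.9, front_target_fraction=0.3, noise_sd=8.0, seed=2
    )
    return tsrzone.generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom_narrow():
    """Small phantom (narrow width) to keep classifier tests fast."""
    cfg = tsrzone.PhantomConfig(
        image_size_px=(560, 80),
        inner_target_fraction=0.6,
        front_target_fraction=0.4,
        noise_sd=4.0,
        seed=3,
    )
    return tsrzone.generate_phantom(cfg)


@pytest.fixture()
def full_tissue():
    def _make(shape, mpp):
        return TumorMask(np.ones(shape, dtype=np.uint8), mpp)

    return _make
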