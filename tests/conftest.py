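import numpy as np
import pytest

from mammospat.phantom import PhantomSpec, generate_phantom
from mammospat.segmentation import RegionLabelMap


@pytest.fixture(scope="session")
def default_phantom():
    """One default 128x128 phantom with its ground truth (shared, read-only)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Low-noise phantom for segmentation-accuracy checks."""
    return generate_phantom(PhantomSpec(seed=3, noise_sd=0.01))


def make_labelmap(labels, spacing=0.25) -> RegionLabelMap:
    return RegionLabelMap(np.asarray(labels, dtype=np.uint8), spacing)


@pytest.fixture
def labelmap_factory():
    return make_labelmap
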