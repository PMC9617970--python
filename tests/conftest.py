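import numpy as np
import pytest

from orientmap.pyramid import PyramidSpec
from orientmap.tuning import compute_probe_features


@pytest.fixture(scope="session")
def spec64():
    """Tiny working configuration: 64 px, 4 levels, 32 channels."""
    return PyramidSpec.for_image(64)


@pytest.fixture(scope="session")
def spec128():
    """Reduced working configuration: 128 px, 5 levels, 40 channels."""
    return PyramidSpec.for_image(128)


@pytest.fixture(scope="session")
def probes64(spec64):
    return compute_probe_features(spec64)


@pytest.fixture(scope="session")
def probes128(spec128):
    return compute_probe_features(spec128)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
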