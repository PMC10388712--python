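import numpy as np
import pytest

from holopollen import (
    OpticsMeta,
    ReferenceWave,
    forward_hologram,
    make_phantom,
)

DEFAULT_TILT = (0.125, 0.125)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference():
    return ReferenceWave(tilt=DEFAULT_TILT, amplitude=1.0)


@pytest.fixture
def hemisphere_hologram(reference):
    """Noiseless 256^2 hologram of a hemispherical viable phantom."""
    phantom = make_phantom("viable", (256, 256), (128, 128), 40, 8.0)
    holo = forward_hologram(phantom.true_phase, 1.0, reference)
    return holo, phantom
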