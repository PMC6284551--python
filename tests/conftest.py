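import numpy as np
import pytest

from stereoplacenta import make_placenta_phantom, make_shell_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shell_80_5():
    return make_shell_phantom(80.0, 5.0)


@pytest.fixture(scope="session")
def small_placenta():
    """A reduced placenta phantom cheap enough for voxel oracles."""
    return make_placenta_phantom(
        semi_axes=(300.0, 300.0, 160.0), n_capillaries=12,
        capillary_radius=14.0, n_channels=8, channel_radius=16.0,
        tau_true=5.0, seed=7)
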