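import numpy as np
import pytest

from cryocn import AcquisitionGeometry, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ball_volume():
    """A solid ball centered in a 16^3 grid (smooth-ish isotropic object)."""
    idx = np.indices((16, 16, 16))
    dist = np.sqrt(((idx - 7.5) ** 2).sum(axis=0))
    return Volume(data=(dist <= 5).astype(float))


@pytest.fixture
def coarse_geometry():
    """A cheap +-60 deg series with a 15 deg step (9 projections)."""
    return AcquisitionGeometry.from_step_range(step=15.0, tilt_range=60.0)
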