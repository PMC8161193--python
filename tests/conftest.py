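import numpy as np
import pytest

import marrowmap as mm
from marrowmap.config import tiny_generator_config


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_generator_config()


@pytest.fixture(scope="session")
def meta_m30():
    return mm.SubjectMeta("sub-000", "M", 30, 25.0)


@pytest.fixture(scope="session")
def noiseless_tiny_study(tiny_config, meta_m30):
    """Noiseless single subject on the fast (coarse) grids."""
    phantom = mm.build_phantom(meta_m30, tiny_config)
    study = mm.render_study(phantom, noise_sigma=0.0, seed=1, config=tiny_config)
    return phantom, study


@pytest.fixture(scope="session")
def noiseless_default_study(meta_m30):
    """Noiseless single subject on the full default station geometry."""
    phantom = mm.build_phantom(meta_m30)
    study = mm.render_study(phantom, noise_sigma=0.0, seed=1)
    return phantom, study


def grid(shape=(4, 4, 3), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return mm.GridGeometry(origin=origin, spacing=spacing, shape=shape)


def vol(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), channel="b50"):
    data = np.asarray(data, dtype=float)
    g = mm.GridGeometry(origin=origin, spacing=spacing, shape=data.shape)
    return mm.ImageVolume(data, g, channel)
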