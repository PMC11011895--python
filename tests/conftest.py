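import numpy as np
import pytest

from tracerflow.simulate import default_protocol, make_phantom
from tracerflow.types import RoiMask, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture
def protocol():
    return default_protocol()


@pytest.fixture
def iso_phantom():
    return make_phantom("isotropic", grid_shape=(12, 12, 10), radius_vox=4.0)


@pytest.fixture
def small_diffusion_config():
    """Uniform-spacing pure-diffusion setup used by the analytic oracles."""
    return SimulationConfig(
        grid_shape=(41, 41, 41),
        voxel_spacing_mm=(0.125, 0.125, 0.125),
        diffusion_coefficient=2.0e-8,
        infusion_rate=0.0,
        snapshot_times_ms=(2.25e6,),
    )


def ball_mask(shape, center, radius):
    idx = np.indices(shape)
    r2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return RoiMask(voxels=r2 <= radius**2, label="ball")


@pytest.fixture
def ball_roi():
    return ball_mask
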