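import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cranioflow.synth import (  # noqa: E402
    AcquisitionSpec,
    WaveformSpec,
    make_straight_vessel,
    rasterize,
)


@pytest.fixture(scope="session")
def straight_vessel():
    """R = 3 mm straight tube along +z with a systolic-pulse waveform."""
    wf = WaveformSpec(mean_flow=3.0, pi_target=0.8, shape="systolic_pulse", n_frames=25)
    return make_straight_vessel("tube", (11.5, 11.5), (0.0, 11.0), 3.0, wf)


@pytest.fixture(scope="session")
def acq_1mm():
    return AcquisitionSpec(voxel_size=(1.0, 1.0, 1.0), grid_shape=(24, 24, 12),
                           n_frames=25, venc=100.0)


@pytest.fixture(scope="session")
def clean_volume(straight_vessel, acq_1mm):
    """Noise-free 1 mm rasterisation of the straight vessel."""
    return rasterize([straight_vessel], acq_1mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
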