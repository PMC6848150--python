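import numpy as np
import pytest

from caphys.config import AnalysisParams, ChannelModel, ImagingConfig, VoltageProtocol
from caphys.synth import generate_imaging_session


@pytest.fixture(scope="session")
def small_imaging_config():
    """Small, fast session used by several imaging tests."""
    return ImagingConfig(
        image_height_px=96,
        image_width_px=96,
        n_cells=20,
        responder_fraction=0.2,
        baseline_duration_min=6.0,
        post_duration_min=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_imaging_config):
    return generate_imaging_session(small_imaging_config, condition_label="test")


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free, bleach-free session for exactness checks."""
    cfg = ImagingConfig(
        image_height_px=96,
        image_width_px=96,
        n_cells=15,
        responder_fraction=0.2,
        noise_sd=0.0,
        photobleach_rate=0.0,
        baseline_duration_min=6.0,
        post_duration_min=8.0,
        seed=11,
    )
    return generate_imaging_session(cfg)


@pytest.fixture
def fast_params():
    return AnalysisParams(rolling_ball_radius_px=12)


@pytest.fixture
def protocol():
    return VoltageProtocol()


@pytest.fixture
def clean_model():
    return ChannelModel(g_leak=0.0, c_membrane=0.0, noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
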