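import warnings

import numpy as np
import pytest

from ocuflow import (PipelineConfig, VideoSimConfig, render_vessel_video)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def clean_video():
    """Noiseless, jitter-free straight vessel (fast geometry oracle)."""
    cfg = VideoSimConfig(
        n_frames=40, noise_sd=0.0, jitter_sd_px=0.0, blur_sigma_px=0.0,
        texture_sd=0.0, vessel_diameter_um=22.0, axial_velocity_mm_s=0.5,
        centerline_waypoints=[(20, 96), (90, 96), (170, 96)], seed=11)
    return render_vessel_video(cfg)


@pytest.fixture(scope="session")
def default_video():
    """Default study conditions: curved vessel, jitter, blur, noise."""
    cfg = VideoSimConfig(n_frames=80, seed=5)
    return render_vessel_video(cfg)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
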