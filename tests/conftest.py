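import numpy as np
import pytest

from thermokinesis import bout_pipeline as bp
from thermokinesis import presets, synthetic_data as sd, tracking_io as tio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arena():
    return tio.ArenaConfig()


@pytest.fixture
def detection_params():
    """Detection operating point used for clean synthetic renders.

    The renderer has far less measurement noise than real video, so the
    speed variance is bout-dominated and the 2x-SD default would sit
    above small forward bouts; 1x SD plus the displacement filter is the
    equivalent operating point for synthetic data.
    """
    return bp.DetectionParams(threshold_mult=1.0)


@pytest.fixture(scope="session")
def preset_18c():
    return presets.preset_by_name("18C")


@pytest.fixture(scope="session")
def preset_26c():
    return presets.preset_by_name("26C")


@pytest.fixture(scope="session")
def small_cohort():
    """3 fish x 5 min at 26 degC: frames plus ground truth."""
    return sd.make_cohort("26C", n_fish=3, duration=300.0, seed=77)


@pytest.fixture(scope="session")
def clean_render():
    """Single noiseless fish, 2 min at 18 degC, with its planted truth."""
    rng = np.random.default_rng(4)
    preset = presets.preset_by_name("18C")
    bouts = sd.generate_bout_sequence(preset, duration=120.0, rng=rng)
    frames = sd.render_frames(
        bouts, sd.RenderConfig(centroid_noise_sd=0.0), duration=120.0, rng=rng
    )
    return bouts, frames
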