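import numpy as np
import pytest

from weedscan import PipelineConfig, get_profile, render_scene
from weedscan.scenes import SceneSpec, WeedSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def day_exg_config():
    return PipelineConfig(algorithm="exg", profile=get_profile("day", "exg"))


@pytest.fixture
def gray_frame():
    return np.full((64, 64, 3), 120, dtype=np.uint8)


@pytest.fixture
def one_disc_scene():
    """A single high-contrast green disc (radius 10) on red-orange soil."""
    spec = SceneSpec(
        dims=(128, 96),
        weeds=(WeedSpec(centroid=(60.0, 50.0), radius=10, hue_deg=120.0,
                        saturation=140, value=140),),
        blur_sigma=0.5,
        seed=42,
    )
    return render_scene(spec)
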