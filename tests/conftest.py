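import numpy as np
import pytest

from papillae import HeatmapConfig, SceneConfig, desk_profile


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk():
    return desk_profile(seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic desk-scale scene shared across read-only tests."""
    from papillae import generate_scene
    cfg = SceneConfig(image_size=(128, 128), n_spots=12,
                      spot_radius_px=(2.0, 4.0), min_separation=7.0, seed=42)
    return generate_scene(cfg)


@pytest.fixture()
def hm_config():
    return HeatmapConfig(sigma=2.0, peak_min_distance=2)
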