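import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cropfusion.raster_model import BandMeta, MultibandRaster, make_bands
from cropfusion.synthetic_scene import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_raster(rng):
    """3-band 4x4 raster with blue/red/nir roles."""
    values = rng.random((3, 4, 4))
    return MultibandRaster(
        values=values,
        bands=make_bands(("blue", "red", "nir")),
        pixel_size=10.0,
        origin=(100.0, 200.0),
    )


@pytest.fixture
def noise_free_config():
    """One wheat field, zero noise everywhere: NDVI is exactly the target."""
    traj = {
        "wheat": {t: (m, 0.0) for t, m in
                  zip(("T1", "T2", "T3", "T4", "T5"),
                      (0.3, 0.45, 0.6, 0.8, 0.62))},
        "maize": {t: (m, 0.0) for t, m in
                  zip(("T1", "T2", "T3", "T4", "T5"),
                      (0.28, 0.35, 0.4, 0.45, 0.47))},
    }
    return SceneConfig(
        extent=(24, 24),
        n_fields=1,
        ndvi_trajectory=traj,
        texture_params={"wheat": (1.5, 0.0), "maize": (5.0, 0.0)},
        background_ndvi=(0.12, 0.0),
        background_texture=(3.0, 0.0),
        sensor_noise=0.0,
        seed=3,
    )


@pytest.fixture
def default_config():
    return SceneConfig(seed=11)
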