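import numpy as np
import pytest

from strandscan import (
    GeoTransform,
    MultispectralRaster,
    SceneConfig,
    WORLDVIEW2_BANDS,
    generate_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    """One realistic heterogeneous scene shared across read-only tests."""
    cfg = SceneConfig(n_whales=10, n_logs=4, n_waves=3, n_clouds=1, seed=42,
                      rows=160, cols=160)
    ms, pan, truth = generate_scene(cfg)
    return cfg, ms, pan, truth


@pytest.fixture
def tiny_transform():
    return GeoTransform(origin_x=1000.0, origin_y=2000.0, pixel_size=2.0)


def make_raster(values, pixel_size=2.0):
    """Wrap a (8, h, w) array as a multispectral raster."""
    values = np.asarray(values, dtype=np.float32)
    return MultispectralRaster(
        values, GeoTransform(0.0, 0.0, pixel_size), WORLDVIEW2_BANDS
    )
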