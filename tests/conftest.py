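import numpy as np
import pytest

from grasscasa import GeoRef, Grid, GridStack, ModelParams, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def georef() -> GeoRef:
    return GeoRef(west=100.0, north=32.0, dx=0.25, dy=0.25)


@pytest.fixture
def make_grid(georef):
    def _make(values, mask=None, units=""):
        return Grid(np.asarray(values, dtype=float), georef, mask, units)

    return _make


@pytest.fixture
def make_stack(georef):
    def _make(values, mask=None, units=""):
        values = np.asarray(values, dtype=float)
        if values.ndim == 0:
            values = np.full((12, 2, 2), float(values))
        elif values.ndim == 1:  # one value per month, broadcast over a 2x2 grid
            values = np.repeat(values, 4).reshape(12, 2, 2)
        return GridStack(values, georef, mask, units)

    return _make


@pytest.fixture(scope="session")
def scene16():
    """Small noise-free scene for fast unit tests."""
    cfg = SceneConfig(grid_shape=(16, 16), seed=3, station_noise_sd=0.0,
                      yield_rel_noise_sd=0.0)
    return cfg, *generate_scene(cfg)


@pytest.fixture(scope="session")
def scene64():
    """Default-size noise-free scene for end-to-end recovery tests."""
    cfg = SceneConfig(grid_shape=(64, 64), seed=42, station_noise_sd=0.0,
                      yield_rel_noise_sd=0.0)
    return cfg, *generate_scene(cfg)
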