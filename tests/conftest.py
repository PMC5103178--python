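import numpy as np
import pytest

from sourmon.config import preset_config
from sourmon.segmentation import train_classifier
from sourmon.simulate import CultureSimConfig, SensorSimConfig, TileGeometry, render_frame


@pytest.fixture(scope="session")
def small_geometry():
    """Single small tile: fast rendering for property tests."""
    return TileGeometry(tile_h=128, tile_w=128, n_rows=1, n_cols=1)


@pytest.fixture(scope="session")
def tile_geometry():
    """Default 2x2 tiling with 10% overlap."""
    return TileGeometry()


@pytest.fixture(scope="session")
def cho_config():
    return CultureSimConfig()


@pytest.fixture(scope="session")
def quiet_sensors():
    """Noise-free, spike-free sensor chain with no lag or delay."""
    return SensorSimConfig(
        noise_sd_uM=0.0, spike_rate_per_h=0.0, sensor_lag_min=0.0, outlet_transport_delay_min=0.0
    )


@pytest.fixture(scope="session")
def rendered_frames(tile_geometry, cho_config):
    """Frames across the culture arc with ground truth, shared across tests."""
    rng = np.random.default_rng(42)
    return {
        c: render_frame(c, tile_geometry, cho_config, rng) for c in (0.05, 0.15, 0.3, 0.5, 0.7)
    }


@pytest.fixture(scope="session")
def trained_classifier(rendered_frames):
    frames = [rendered_frames[c] for c in (0.15, 0.5)]
    return train_classifier([f.image for f in frames], [f.mask for f in frames], seed=0)


@pytest.fixture()
def cho_run_config():
    cfg = preset_config("cho_culture")
    cfg.seed = 123
    return cfg
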