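import numpy as np
import pytest

import urbancanopy as uc


@pytest.fixture(scope="session")
def day_night_scene():
    """Default 60x60 scene with one night and one midday overpass."""
    cfg = uc.SceneConfig(grid_rows=60, grid_cols=60, seed=7,
                         overpass_times=(2.0, 13.0))
    truth, fractions, covariates, overpasses = uc.build_scene_products(cfg)
    return cfg, truth, fractions, covariates, overpasses


@pytest.fixture(scope="session")
def decomposed_midday(day_night_scene):
    """Midday decomposition of the default scene (shared across tests)."""
    cfg, truth, fractions, covariates, overpasses = day_night_scene
    stack = uc.decompose_image(overpasses[1], fractions, cfg.class_emissivities)
    return cfg, truth, fractions, overpasses[1], stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
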