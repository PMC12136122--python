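import numpy as np
import pytest

from gclp.synthetic import (PhantomConfig, make_surfaces, plant_vessels,
                            render_volumes)

# small but fully featured phantom shared across test modules
SMALL = dict(grid_n=120, n_z=256, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    return PhantomConfig(**SMALL)


@pytest.fixture(scope="session")
def small_eye(small_cfg):
    """(config, surfaces, scene, volume) of one default small phantom eye."""
    surfaces = make_surfaces(small_cfg)
    scene = plant_vessels(small_cfg, surfaces)
    volume = render_volumes(scene, surfaces, small_cfg)
    return small_cfg, surfaces, scene, volume


@pytest.fixture(scope="session")
def flat_surfaces():
    """Parallel-plane surfaces for geometry tests."""
    cfg = PhantomConfig(grid_n=40, n_z=200, flat=True, nfl_iso_um=30,
                        pit_depth_um=0.0, seed=1)
    return cfg, make_surfaces(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
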