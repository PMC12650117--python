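import numpy as np
import pytest

from ecovuln import SynthConfig, simulate_scene
from ecovuln.grids import Grid


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small fast scene: 12x12 grid, 12 years (8 five-year windows)."""
    return SynthConfig(grid_rows=12, grid_cols=12, start_year=1983,
                       end_year=1994, phase_breaks=(1990,),
                       phase_slopes=(0.0, 0.0), rng_seed=11)


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return simulate_scene(tiny_config)


@pytest.fixture(scope="session")
def gradient_config() -> SynthConfig:
    """Full-length scene with the canonical 1983-2022 configuration."""
    return SynthConfig(grid_rows=40, grid_cols=40, rng_seed=7)


@pytest.fixture(scope="session")
def gradient_scene(gradient_config):
    return simulate_scene(gradient_config)


@pytest.fixture
def small_grid() -> Grid:
    return Grid(10, 10, origin_lat=33.0, origin_lon=99.0, cell_size=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
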