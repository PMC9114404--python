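import numpy as np
import pytest

from benthoscape import seascape as sc
from benthoscape.grids import Grid


@pytest.fixture
def small_grid():
    """3x3 grid of 1..9, 10-m cells, origin at (0, 30)."""
    return Grid(np.arange(1.0, 10.0).reshape(3, 3), 10.0, 0.0, 30.0)


@pytest.fixture(scope="session")
def small_seascape():
    """Compact seascape + env stack shared by read-only tests."""
    spec = sc.SeascapeSpec(nrows=60, ncols=100, seed=7)
    depth = sc.generate_bathymetry(spec)
    env = sc.generate_env_layers(depth, spec)
    return spec, depth, env


@pytest.fixture(scope="session")
def surveyed_seascape(small_seascape):
    """Seascape plus a simulated survey with planted overlaps."""
    spec, depth, env = small_seascape
    niches = sc.make_community(seed=8)
    niches = sc.calibrate_density(env, niches)
    design = sc.SurveyDesign(n_transects=10, images_per_transect=100,
                             overlap_fraction=0.05, seed=9)
    table, truth = sc.simulate_survey(env, niches, design)
    return env, niches, design, table, truth


def ramp_grid(nrows=8, ncols=8, cell=10.0, dz_per_cell_x=0.0,
              dz_per_cell_y=0.0, base=1000.0):
    """Planar depth ramp: depth increases dz per cell eastwards/southwards."""
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    vals = base + dz_per_cell_x * cols + dz_per_cell_y * rows
    return Grid(vals.astype(float), cell, 0.0, nrows * cell)
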