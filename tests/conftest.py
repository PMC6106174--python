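import numpy as np
import pytest

import betadrift as bd
from betadrift.atlas import Grid, OccurrenceAtlas
from betadrift.traits import DistanceMatrix


def make_grid(rows, cols, cell_size=10, land=None):
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    e = cc * cell_size
    n = rr * cell_size
    ids = tuple(f"h{x}_{y}" for x, y in zip(e, n))
    if land is None:
        land = np.ones(rows * cols)
    return Grid(ids, e, n, cell_size, land)


def make_atlas(presence, period="period1", cell_size=10, land=None):
    presence = np.asarray(presence, dtype=np.uint8)
    rows = int(np.sqrt(presence.shape[0]))
    grid = make_grid(rows, presence.shape[0] // rows, cell_size, land)
    species = tuple(f"sp{j}" for j in range(presence.shape[1]))
    return OccurrenceAtlas(grid, species, period, presence)


def random_distance_matrix(rng, n):
    """A valid random Gower-style distance matrix (metric-free but symmetric,
    zero-diagonal, entries in [0, 1])."""
    a = rng.uniform(0, 1, size=(n, 3))
    d = np.abs(a[:, None, :] - a[None, :, :]).mean(axis=2)
    return DistanceMatrix(tuple(f"sp{j}" for j in range(n)), d)


@pytest.fixture(scope="session")
def small_sim():
    cfg = bd.SimConfig(grid_size=12, n_species=25, seed=11,
                       homog_region=(2, 2, 8, 8), homog_strength=0.8,
                       trait_coupling=0.5)
    a1, a2 = bd.simulate_atlas_pair(cfg)
    traits = bd.simulate_traits(cfg)
    return cfg, a1, a2, traits


@pytest.fixture(scope="session")
def small_dmat(small_sim):
    _, _, _, traits = small_sim
    return bd.gower(traits)
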