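import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chs_sdm.grids import Grid, GridTransform, GridStack
from chs_sdm.synthetic_world import (VirtualSpeciesSpec, WorldSpec,
                                     generate_world)


@pytest.fixture(scope="session")
def small_spec():
    return WorldSpec(n_rows=40, n_cols=40, seed=7)


@pytest.fixture(scope="session")
def small_world(small_spec):
    """A 40x40 synthetic world with a 60-presence virtual species."""
    vs = VirtualSpeciesSpec(n_presences=60)
    stack, truth, occ, zones = generate_world(small_spec, vs, n_zones=4)
    return {"spec": small_spec, "species": vs, "stack": stack,
            "truth": truth, "occ": occ, "zones": zones}


@pytest.fixture
def unit_grid():
    """5x5 grid, 1-degree cells, west=0 north=5."""
    return Grid(values=np.arange(25, dtype=float).reshape(5, 5),
                transform=GridTransform(0.0, 5.0, 1.0))


def make_grid(values, west=0.0, north=None, cell=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    north = values.shape[0] * cell if north is None else north
    return Grid(values=values, transform=GridTransform(west, north, cell),
                nodata=nodata)
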