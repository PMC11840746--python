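import numpy as np
import pytest

from vra.io import load_extinction_table
from vra.phantom import generate_phantom, two_region_spec
from vra.pipeline import run_vra
from vra.types import VoxelGrid


@pytest.fixture(scope="session")
def eps_table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid(shape=(32, 48, 48))


@pytest.fixture(scope="session")
def small_phantom(small_grid, eps_table):
    """One seeded small two-region phantom plus its pipeline result."""
    spec = two_region_spec(grid=small_grid, seed=7)
    pa, fluence, tumor, truth = generate_phantom(spec, eps=eps_table, seed=7)
    result = run_vra(pa, tumor, eps_table, fluence=fluence)
    return {
        "spec": spec,
        "pa": pa,
        "fluence": fluence,
        "tumor": tumor,
        "truth": truth,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
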