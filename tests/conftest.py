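import numpy as np
import pytest

from landgen.raster import GridSpec, RasterStack
from landgen.synthetic import (
    SyntheticScenario,
    generate_climate_stack,
    generate_populations_and_genotypes,
)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Down-scaled study: 10 populations on a 20x24 grid, 6 layers."""
    return SyntheticScenario(
        seed=42, n_cells=(20, 24), n_vars=6, n_pops=10, n_ind_per_pop=8,
        K_true=3, autocorr_range=4.0,
    )


@pytest.fixture(scope="session")
def climate(small_scenario):
    return generate_climate_stack(small_scenario)


@pytest.fixture(scope="session")
def genetic_data(small_scenario, climate):
    current, _ = climate
    return generate_populations_and_genotypes(small_scenario, current)


@pytest.fixture()
def flat_grid() -> GridSpec:
    """Small near-equator grid where cells are nearly equal-area."""
    return GridSpec(0.0, -0.015, 0.01, 3, 3)


def make_stack(arrays: dict[str, np.ndarray], cellsize: float = 0.1,
               xmin: float = 100.0, ymin: float = 30.0) -> RasterStack:
    first = next(iter(arrays.values()))
    grid = GridSpec(xmin, ymin, cellsize, first.shape[0], first.shape[1])
    return RasterStack(grid, {k: np.asarray(v, dtype=float) for k, v in arrays.items()})
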