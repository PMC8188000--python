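import numpy as np
import pytest

from buteo_abm import (
    KitLandscapeSpec,
    Resource,
    ResourceMap,
    SimulationParams,
    StochasticLandscapeSpec,
    TerritoryKit,
    generate_synthetic_landscape,
)
from buteo_abm.synth import kit_landscape


@pytest.fixture
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def three_kit_map() -> ResourceMap:
    """Three mutually unreachable, exactly viable territory kits."""
    return kit_landscape(3, seed=11)


@pytest.fixture(scope="session")
def stochastic_map() -> ResourceMap:
    """A mid-sized random landscape with the default cover structure."""
    return generate_synthetic_landscape(StochasticLandscapeSpec(n_cols=120, n_rows=120), seed=7)


def random_small_map(seed: int, n: int = 25) -> ResourceMap:
    """A small random per-pixel map for oracle comparisons (<= 30x30)."""
    rng = np.random.default_rng(seed)
    grid = rng.choice(
        [int(r) for r in Resource],
        size=(n, n),
        p=[0.28, 0.10, 0.22, 0.35, 0.05],
    ).astype(np.int8)
    return ResourceMap(grid, pixel_size=25.0)


@pytest.fixture
def single_kit_map() -> ResourceMap:
    return generate_synthetic_landscape(
        KitLandscapeSpec(n_cols=100, n_rows=100, kits=[TerritoryKit()]), seed=3
    )
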