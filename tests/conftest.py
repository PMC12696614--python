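import numpy as np
import pytest

from browndry.grid import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """Desk-scale grid: 4 x 6 cells, 1982-2020."""
    return GridSpec.regular(4, 6)


@pytest.fixture(scope="session")
def scenario():
    """One realization of the default coupled drying-box scenario (seed 1)."""
    from browndry.pipeline import RunConfig
    from browndry.synthetic import drying_scenario, generate_member

    cfg = RunConfig(seed=1)
    grid = cfg.grid()
    specs, coupling, box = drying_scenario()
    lai, drivers = generate_member(grid, specs, coupling, cfg.seed)
    return {"config": cfg, "grid": grid, "box": box, "lai": lai, "drivers": drivers}
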