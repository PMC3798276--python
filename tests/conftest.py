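import pytest

from cyclesim import (
    AgeGrid,
    ModelConfig,
    PhaseDurationSpec,
    desynchronize,
    igrov1_like_config,
)


@pytest.fixture(scope="session")
def grid():
    return AgeGrid(delta_h=0.5)


@pytest.fixture(scope="session")
def coarse_grid():
    return AgeGrid(delta_h=1.0)


@pytest.fixture(scope="session")
def plain_config(grid):
    """24 h cycle, no quiescence/death: the simplest growing population."""
    return ModelConfig(
        durations={
            "G1": PhaseDurationSpec(mean_h=11.0, cv=0.25),
            "S": PhaseDurationSpec(mean_h=9.0, cv=0.15),
            "G2M": PhaseDurationSpec(mean_h=4.0, cv=0.25),
        },
        grid=grid,
        n_cycles=5,
    )


@pytest.fixture(scope="session")
def base_config(grid):
    """Realistic baseline with quiescence and slow quiescent death."""
    return igrov1_like_config(grid=grid, n_cycles=5)


@pytest.fixture(scope="session")
def coarse_config(coarse_grid):
    """1 h grid baseline used where speed matters more than resolution."""
    return igrov1_like_config(grid=coarse_grid, n_cycles=5)


@pytest.fixture(scope="session")
def plain_start(plain_config):
    return desynchronize(plain_config)


@pytest.fixture(scope="session")
def base_start(base_config):
    return desynchronize(base_config)
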