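import numpy as np
import pytest

from petkin.compartment import model_tac
from petkin.simulate import default_frame_schedule, synthetic_input, table2_grid


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def inputs():
    """Packaged synthetic bolus input: (parent plasma, whole blood)."""
    return synthetic_input(seed=0)


@pytest.fixture(scope="session")
def plasma(inputs):
    return inputs[0]


@pytest.fixture(scope="session")
def blood(inputs):
    return inputs[1]


@pytest.fixture(scope="session")
def grid():
    return table2_grid()


@pytest.fixture(scope="session")
def noiseless_tacs(grid, plasma, blood, schedule):
    """Noiseless simulated TAC per grid configuration (list of curves)."""
    return [model_tac(c, plasma, blood, schedule) for c in grid.configs]


@pytest.fixture(scope="session")
def reference_tac(noiseless_tacs, grid):
    """The pseudo-reference TAC (lowest-binding configuration)."""
    return noiseless_tacs[grid.reference_index]
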