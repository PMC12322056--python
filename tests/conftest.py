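import numpy as np
import pytest

from bcellfate.cell import CellParams, find_cell_rest
from bcellfate.receptor import ReceptorParams, find_steady_state


@pytest.fixture(scope="session")
def receptor_params() -> ReceptorParams:
    return ReceptorParams()


@pytest.fixture(scope="session")
def receptor_rest(receptor_params):
    state, converged = find_steady_state(receptor_params)
    assert converged
    return state


@pytest.fixture(scope="session")
def cell_params() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def cell_rest(cell_params):
    rest, converged = find_cell_rest(cell_params)
    assert converged
    return rest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
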