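import numpy as np
import pytest

from mtends import (
    SolverConfig,
    effective_params_from_model,
    table1_defaults,
)


@pytest.fixture(scope="session")
def base_params():
    return table1_defaults()


@pytest.fixture(scope="session")
def eff(base_params):
    return effective_params_from_model(base_params)


@pytest.fixture()
def fast_solver():
    """Coarse, snapshot-free solver settings for quick integration tests."""
    return SolverConfig(n_cells=32, store_snapshots=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
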