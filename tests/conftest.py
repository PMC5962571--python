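import numpy as np
import pytest

from cyclefish import SynthConfig, default_phase_map, generate_cell_table, table1_model


@pytest.fixture(scope="session")
def model():
    return table1_model()


@pytest.fixture(scope="session")
def pmap():
    return default_phase_map()


@pytest.fixture(scope="session")
def cell_table(model):
    """2000 analytic synthetic cells at the published constants (seed 1)."""
    return generate_cell_table(SynthConfig(model=model, n_cells=2000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
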