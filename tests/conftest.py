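import numpy as np
import pytest

import hierpower as hp


@pytest.fixture(scope="session")
def truth_model():
    return hp.default_truth_model()


@pytest.fixture(scope="session")
def tiny():
    """Hand-worked 5-gene, 3-individual matrix with frozen expected values."""
    return hp.tiny_worked_fixture()


@pytest.fixture(scope="session")
def small_pilot(truth_model):
    """A small but realistic pilot matrix (shared across tests; read-only)."""
    spec = hp.FixtureSpec(n_genes=300, n_individuals=8, cells_per_individual=60, seed=7)
    return hp.generate_pilot(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
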