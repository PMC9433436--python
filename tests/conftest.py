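import numpy as np
import pytest

from htskin import krel, simulate


@pytest.fixture(scope="session")
def landscape_model():
    return simulate.realistic_landscape()


@pytest.fixture(scope="session")
def landscape_truth(landscape_model):
    """Paper-like specificity landscape assigned to the full 4096-variant pool."""
    return simulate.assign_true_krel(model=landscape_model, seed=11)


@pytest.fixture(scope="session")
def sampled_rates(landscape_truth):
    """A full simulated experiment at default depth, and its recovered rates."""
    table = simulate.simulate_pool_counts(landscape_truth, seed=11)
    rates = krel.krel_from_counts(table)
    return table, rates


@pytest.fixture(scope="session")
def uniform_truth():
    """Homogeneous pool: every variant reacts at the reference rate."""
    return simulate.assign_true_krel(table=np.ones(simulate.N_VARIANTS))
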