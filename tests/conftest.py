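import numpy as np
import pytest

from poolgwas import simulate as sim


@pytest.fixture(scope="session")
def clean_design():
    """Study design (two batches, 3 replicates) without bad arrays, so QC
    behaviour is deterministic where a test needs it."""
    return sim.default_design(bad_array_rate=0.0)


@pytest.fixture(scope="session")
def null_truth():
    """2,000 null SNPs (no risk loci)."""
    return sim.simulate_truth(2000, seed=11)


@pytest.fixture(scope="session")
def null_panel(null_truth, clean_design):
    return sim.simulate_pool_intensities(null_truth, clean_design, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
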