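import numpy as np
import pytest

from evoko import synthetic_data as sd


@pytest.fixture(scope="session")
def small_universe():
    """A 1000-gene, 60-term annotation universe used across modules."""
    return sd.generate_go_universe(
        n_genes=1000, n_terms=60, term_size_range=(10, 60), large_term_fraction=0.05, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_universe):
    return sd.generate_truth(
        small_universe, n_native=30, n_spurious=60, n_focus_terms=3, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
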