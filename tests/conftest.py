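import numpy as np
import pytest

from mirweave.synthetic import StudyDesign, simulate_study


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """Reduced study size for fast unit tests (full size in acceptance)."""
    return StudyDesign(n_mirnas=10, n_interactions=10, n_decoys=10,
                       n_null_genes=30, n_background_tags=60,
                       coexpr_blocks=2, coexpr_block_size=40, n_anticorr=6)


@pytest.fixture(scope="session")
def small_study(small_design):
    return simulate_study(small_design, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
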