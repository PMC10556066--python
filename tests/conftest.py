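import numpy as np
import pytest

from blastsig.syndata import SimConfig, expression_profiles, generate_bulk_cohort, generate_single_cell


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale configuration for fast unit tests."""
    return SimConfig(
        n_genes=300,
        n_blast_cells=150,
        n_nonblast_cells=150,
        n_patients=2,
        n_bulk_samples=60,
        n_bulk_eoi=12,
        seed=17,
    )


@pytest.fixture(scope="session")
def small_cells(small_config):
    return generate_single_cell(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    prof = expression_profiles(small_config)
    return generate_bulk_cohort(small_config, prof["blast"], prof["normal"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
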