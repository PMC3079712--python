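import pytest

from mtevol.datasets import (
    bundled_catalogue,
    bundled_cohort,
    bundled_conservation,
    bundled_mask,
    bundled_phylotree,
    bundled_rates,
    bundled_reference,
)
from mtevol.simulate import SimulationConfig, simulate_reference


@pytest.fixture(scope="session")
def rcrs():
    """Bundled synthetic rCRS-like reference (real coordinates)."""
    return bundled_reference()


@pytest.fixture(scope="session")
def mini_tree():
    return bundled_phylotree()


@pytest.fixture(scope="session")
def mask():
    return bundled_mask()


@pytest.fixture(scope="session")
def cohort():
    return bundled_cohort()


@pytest.fixture(scope="session")
def rates():
    return bundled_rates()


@pytest.fixture(scope="session")
def catalogue():
    return bundled_catalogue()


@pytest.fixture(scope="session")
def conservation():
    return bundled_conservation()


@pytest.fixture(scope="session")
def small_config():
    """Small, fast synthetic genome for property tests."""
    return SimulationConfig(
        seed=7,
        genome_length=3000,
        control_length=400,
        n_protein_genes=2,
        n_trna_genes=3,
        n_rrna_genes=1,
        rrna_length=300,
        tree_depth=2,
        branching_factor=2,
        n_samples=6,
        nonsyn_keep_prob=1.0,
        n_hotspots=0,
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    return simulate_reference(small_config)
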