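import numpy as np
import pytest

from hgtscan import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, small simulation config for unit tests."""
    return syn.SimulationConfig(
        seed=11,
        n_host_genes=4,
        n_planted_hgt={"bacteria": 2, "fungi": 1},
        n_no_homolog=2,
        taxon_counts={"arthropod": 3, "other_eukaryote": 3,
                      "fungi": 5, "bacteria": 6},
        protein_length=120,
        read_depth=12.0,
        n_host_contigs=8,
        pairs_per_omega=1,
        count_model=syn.CountModel(n_genes=12, n_de=2),
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return syn.generate_dataset(tiny_config)
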