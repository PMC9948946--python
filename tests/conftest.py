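import numpy as np
import pytest

from lamnet import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """A fast dataset configuration for unit tests."""
    return sd.SimConfig(
        n_cells=300,
        n_genes=80,
        n_tfs=4,
        regulon_size=10,
        lam_tf_ids=("TF01", "TF02"),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def toy_genome():
    return sd.simulate_genome(
        n_genes=20, seq_length=120_000, motif_consensus="CACGTG",
        planted_fraction=0.5, seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
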