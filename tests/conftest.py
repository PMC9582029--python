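import numpy as np
import pandas as pd
import pytest

from skinmgwas.sim import (
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_microbiome,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_individuals=200, n_variants=100, n_asvs=20, seed=7)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_covariates(small_config, small_genotypes):
    return simulate_covariates(small_config, samples=list(small_genotypes.dosages.index))


@pytest.fixture(scope="session")
def small_abundance(small_config, small_genotypes, small_covariates):
    return simulate_microbiome(small_genotypes, small_covariates, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_abundance(counts, columns=None, taxonomy=None, samples=None):
    """Tiny AbundanceTable helper used across unit tests."""
    from skinmgwas.datatypes import AbundanceTable

    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    columns = columns or [f"ASV{j:03d}" for j in range(1, counts.shape[1] + 1)]
    frame = pd.DataFrame(counts, index=samples, columns=columns)
    return AbundanceTable(counts=frame, taxonomy=taxonomy)
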