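import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snp_prior_gs.qc import compute_allele_frequencies, impute_missing_mean
from snp_prior_gs.simulate import SimScenario, simulate_dataset

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A small inbred-line population with known truth, shared across tests."""
    scenario = SimScenario.preset(
        "inbred_line", n_generations=6, offspring_per_generation=60,
        markers_per_chromosome=100, n_chromosomes=4, n_qtl=40, seed=3)
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def small_genotypes(small_dataset):
    """Complete (imputed) genotypes and frequencies for the small population."""
    g = small_dataset.genotypes
    f = compute_allele_frequencies(g)
    return impute_missing_mean(g, f), f


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
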