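import numpy as np
import pytest

from eqtnprior.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimulationConfig(
        seed=777,
        n_genes=30,
        n_individuals=80,
        snps_per_region=80,
        flank=15_000,
        gene_length=4_000,
        annotation_coverage={"open_chromatin": 0.08},
        true_lambdas={"open_chromatin": 1.0},
        true_pi0=0.3,
    )
    return simulate_study(cfg)
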