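import numpy as np
import pytest

from episcan import SimConfig, simulate_dataset, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """100 individuals x 50 SNPs on 5 chromosomes, moderate LD."""
    cfg = SimConfig(n_individuals=100, n_chromosomes=5, snps_per_chrom=10,
                    seed=7, ld_rho=0.4, n_sire_families=10)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def sim_dataset():
    """Panel + truth + records with one planted AA pair."""
    cfg = SimConfig(n_individuals=800, n_chromosomes=4, snps_per_chrom=8,
                    seed=11, ld_rho=0.3, n_sire_families=16)
    # plant at common SNPs (MAF ~ 0.3 / 0.5) so the pair is recoverable at n=800
    return simulate_dataset(cfg, specs=[(20, 27, "AA", 1.2)])
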