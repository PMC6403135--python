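import numpy as np
import pytest

import diurnalmeth as dm


@pytest.fixture(scope="session")
def small_genome():
    """2 x 60 kb genome with genes and TEs, fixed seed."""
    genome, genes, tes = dm.synthetic_data.simulate_genome(
        n_chrom=2, chrom_length=60_000, n_genes=14, n_tes=8, seed=101
    )
    return genome, genes, tes


@pytest.fixture(scope="session")
def design():
    return dm.default_design()


@pytest.fixture(scope="session")
def small_methylome(small_genome, design):
    """Simulated methylome with planted differential regions."""
    genome, genes, tes = small_genome
    plants = dm.synthetic_data.plan_dmr_regions(
        genome, design, n_regions=4, delta=0.4, seed=7
    )
    sample_sites, controls, truth = dm.synthetic_data.simulate_methylome(
        genome, genes, tes, design, planted_dmrs=plants, coverage_mean=30, seed=11
    )
    return sample_sites, controls, truth, plants


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
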