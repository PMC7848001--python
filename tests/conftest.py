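import numpy as np
import pytest

import droughtmagic as dm


@pytest.fixture(scope="session")
def clean_pop():
    """Artifact-free simulated population, small enough for fast tests."""
    return dm.simulate_population(n_rils=120, n_chrom=3, snps_per_chrom=40, seed=7)


@pytest.fixture(scope="session")
def noisy_pop():
    """Population with injected missingness and heterozygote errors."""
    return dm.simulate_population(
        n_rils=150, n_chrom=4, snps_per_chrom=50, seed=11,
        missing_rate=0.03, het_error_rate=0.02,
    )


@pytest.fixture(scope="session")
def qtl_geno():
    """Medium genotype matrix used for planted-QTL scans."""
    geno, _, _ = dm.simulate_population(n_rils=200, n_chrom=5, snps_per_chrom=60, seed=5)
    return geno


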