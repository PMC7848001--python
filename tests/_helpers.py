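"""Shared helpers for the test suite."""

import numpy as np


def plant_qtl(geno, snp_index, h2, seed=0):
    """Phenotype with one additive QTL explaining h2 of the variance."""
    rng = np.random.default_rng(seed)
    from droughtmagic.gwas import encode_genotypes

    M, _ = encode_genotypes(geno)
    g = M[:, snp_index] - M[:, snp_index].mean()
    sd = g.std()
    if sd == 0:
        raise ValueError("planted QTL is monomorphic")
    g = g / sd * np.sqrt(h2)
    return g + rng.normal(0.0, np.sqrt(1.0 - h2), geno.n_samples)
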