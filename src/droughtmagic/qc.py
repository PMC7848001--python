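"""SNP-level quality control.

Retention rule (strict inequalities): a SNP is kept iff its missing
fraction < ``max_missing`` AND heterozygosity < ``max_het`` AND minor
allele frequency > ``min_maf``.  Heterozygosity is computed per SNP
across samples; per-sample heterozygosity is reported but never
filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import MISSING, GenotypeMatrix, per_snp_het, per_snp_missing


@dataclass
class SnpQcReport:
    per_snp: pd.DataFrame  # snp_id, missing, het, maf, retained + failure flags
    n_input: int
    n_retained: int
    n_fail_missing: int
    n_fail_het: int
    n_fail_maf: int
    per_sample_het: np.ndarray


def maf(column) -> float:
    """Minor allele frequency from 0/1/2 codes over non-missing calls."""
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        return np.nan
    alt = (called == 1).sum() + 2 * (called == 2).sum()
    freq = alt / (2 * called.size)
    return float(min(freq, 1.0 - freq))


class SnpQC(BaseEstimator, TransformerMixin):
    """Marker retention filter in the scikit-learn transformer idiom.

    ``fit`` computes per-SNP missingness, heterozygosity and MAF on a
    :class:`GenotypeMatrix`; ``transform`` drops the failing SNPs.

    Attributes (after fit)
    ----------------------
    report_ : SnpQcReport
    retained_ : ndarray of bool, shape (n_snps,)
    """

    def __init__(self, max_missing: float = 0.10, max_het: float = 0.10,
                 min_maf: float = 0.05):
        self.max_missing = max_missing
        self.max_het = max_het
        self.min_maf = min_maf

    def fit(self, X: GenotypeMatrix, y=None):
        for t in (self.max_missing, self.max_het, self.min_maf):
            if not 0.0 <= t <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")
        if X.n_snps == 0 or X.n_samples == 0:
            raise ValueError("empty genotype matrix")
        miss = per_snp_missing(X)
        het = per_snp_het(X)
        mafs = np.array([maf(X.column(j)) for j in range(X.n_snps)])
        fail_missing = ~(miss < self.max_missing)
        fail_het = ~(het < self.max_het)
        fail_maf = ~(mafs > self.min_maf)
        retained = ~(fail_missing | fail_het | fail_maf)
        per_snp = pd.DataFrame(
            {
                "snp_id": X.snp_id,
                "chrom": X.chrom,
                "pos": X.pos,
                "missing": miss,
                "het": het,
                "maf": mafs,
                "fail_missing": fail_missing,
                "fail_het": fail_het,
                "fail_maf": fail_maf,
                "retained": retained,
            }
        )
        called = X.calls != MISSING
        sample_het = np.where(
            called.sum(axis=1) > 0,
            (X.calls == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            np.nan,
        )
        self.retained_ = retained
        self.report_ = SnpQcReport(
            per_snp=per_snp,
            n_input=X.n_snps,
            n_retained=int(retained.sum()),
            n_fail_missing=int(fail_missing.sum()),
            n_fail_het=int(fail_het.sum()),
            n_fail_maf=int(fail_maf.sum()),
            per_sample_het=sample_het,
        )
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "retained_"):
            raise ValueError("SnpQC is not fitted")
        return X.subset_snps(self.retained_)


def qc_filter(geno: GenotypeMatrix, max_missing: float = 0.10,
              max_het: float = 0.10, min_maf: float = 0.05):
    """Functional wrapper: returns (filtered GenotypeMatrix, SnpQcReport)."""
    qc = SnpQC(max_missing=max_missing, max_het=max_het, min_maf=min_maf).fit(geno)
    return qc.transform(geno), qc.report_
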