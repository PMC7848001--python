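"""Genotype container shared by the simulator, QC, GWAS and LD modules.

Genotypes are biallelic SNP calls coded as the count of the alternate
allele (0, 1, 2) with ``-1`` marking missing calls.  Every SNP carries an
integer chromosome label and a 1-based physical position in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """RIL-by-SNP genotype calls with marker coordinates.

    Parameters
    ----------
    calls : ndarray of shape (n_samples, n_snps), int8
        Genotype codes 0/1/2, with -1 for missing.
    snp_id, chrom, pos : ndarray of shape (n_snps,)
        Marker identifier, chromosome label (1..n) and 1-based bp position.
    samples : list of str
        Sample (line) identifiers, one per row.
    """

    calls: np.ndarray
    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x SNPs)")
        n, m = self.calls.shape
        if not (len(self.snp_id) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("SNP annotation length does not match calls")
        if not self.samples:
            self.samples = [f"RIL{i + 1:03d}" for i in range(n)]
        if len(self.samples) != n:
            raise ValueError("sample list length does not match calls")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if len(set(self.snp_id)) != m:
            raise ValueError("duplicated snp_id")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.calls[:, j]

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            calls=self.calls[:, mask].copy(),
            snp_id=self.snp_id[mask].copy(),
            chrom=self.chrom[mask].copy(),
            pos=self.pos[mask].copy(),
            samples=list(self.samples),
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_id == snp_id)
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not found")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        """Tabular dialect: one row per SNP, samples as columns, NA missing."""
        meta = pd.DataFrame(
            {"snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos}
        )
        calls = self.calls.T.astype(object)
        calls[calls == MISSING] = pd.NA
        return pd.concat(
            [meta, pd.DataFrame(calls, columns=list(self.samples))], axis=1
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        meta = ("snp_id", "chrom", "pos")
        samples = [c for c in df.columns if c not in meta]
        calls = df[samples].to_numpy(dtype=object).T
        out = np.empty(calls.shape, dtype=np.int8)
        isna = pd.isna(calls.astype(object))
        out[isna] = MISSING
        out[~isna] = calls[~isna].astype(np.int8)
        return cls(
            calls=out,
            snp_id=df["snp_id"].to_numpy(),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            samples=samples,
        )


def per_snp_missing(g: GenotypeMatrix) -> np.ndarray:
    return (g.calls == MISSING).mean(axis=0)


def per_snp_het(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of heterozygous calls among non-missing calls per SNP."""
    called = g.calls != MISSING
    n_called = called.sum(axis=0)
    het = (g.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    return out
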