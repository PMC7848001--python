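"""File formats: the genotype tabular dialect, VCF ingest, phenotype and
result tables, truth files and run manifests.

The tabular genotype dialect is tab-separated with header
``snp_id  chrom  pos  <sample...>``; codes are 0/1/2 with ``NA`` for
missing, chromosome labels are integers (``Vu01``-style labels are
accepted and mapped) and positions are 1-based bp.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .simulate import SimTruth


class GenotypeFormatError(ValueError):
    pass


def _parse_chrom(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label)
    s = str(label)
    m = re.fullmatch(r"(?:[Vv]u)?0*(\d+)", s)
    if not m:
        raise GenotypeFormatError(f"unrecognized chromosome label {label!r}")
    return int(m.group(1))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path, fmt: str = "auto") -> GenotypeMatrix:
    """Read genotypes from the tabular dialect or a VCF file."""
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tabular"
    if fmt == "vcf":
        return read_vcf(path)[0]
    if fmt != "tabular":
        raise GenotypeFormatError(f"unknown genotype format {fmt!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "chrom", "pos"]:
            raise GenotypeFormatError(
                "line 1: header must start with snp_id, chrom, pos"
            )
        samples = header[3:]
        snp_id, chrom, pos, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise GenotypeFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                codes = [
                    MISSING if v in ("NA", "", ".") else int(v) for v in fields[3:]
                ]
                if not all(c in (MISSING, 0, 1, 2) for c in codes):
                    raise ValueError
                chrom.append(_parse_chrom(fields[1]))
                pos.append(int(fields[2]))
            except (ValueError, GenotypeFormatError) as err:
                raise GenotypeFormatError(f"line {lineno}: malformed row") from err
            snp_id.append(fields[0])
            rows.append(codes)
    if len(set(snp_id)) != len(snp_id):
        dup = pd.Series(snp_id).value_counts()
        raise GenotypeFormatError(f"duplicated snp_id: {dup[dup > 1].index.tolist()}")
    calls = np.asarray(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        calls=calls,
        snp_id=np.asarray(snp_id, dtype=object),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        samples=samples,
    )


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Map diploid VCF GT fields to 0/1/2 codes.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, missing -> NA; records that are
    not biallelic SNPs are skipped and counted.  Returns (genotypes,
    n_skipped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_id, chrom, pos, rows = [], [], [], []
    skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            skipped += 1
            continue
        codes = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                codes.append(MISSING)
            else:
                codes.append(int(sum(a > 0 for a in alleles[:2])))
        snp_id.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(_parse_chrom(var.CHROM))
        pos.append(var.POS)
        rows.append(codes)
    if len(set(snp_id)) != len(snp_id):
        raise GenotypeFormatError("duplicated snp_id in VCF")
    calls = np.asarray(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    geno = GenotypeMatrix(
        calls=calls,
        snp_id=np.asarray(snp_id, dtype=object),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        samples=samples,
    )
    return geno, skipped


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_truth(truth: SimTruth, geno: GenotypeMatrix, path) -> None:
    """Truth file: tab-separated trait, regime, snp_id, effect."""
    rows = []
    for (trait, regime), qtls in truth.qtl.items():
        for idx, effect in qtls:
            rows.append(
                {
                    "trait": trait,
                    "regime": regime,
                    "snp_id": geno.snp_id[idx],
                    "effect": effect,
                }
            )
    pd.DataFrame(rows, columns=["trait", "regime", "snp_id", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
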