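"""Linkage disequilibrium and the trait-SNP association network.

LD between two SNPs is the squared Pearson correlation of their 0/1/2
genotype codes over shared non-missing samples (composite LD; in nearly
homozygous inbred lines this essentially coincides with haplotype
r-squared).

The association network has trait nodes and SNP nodes.  Three formation
rules connect loci across the genome:

1. a SNP associated with two or more traits links those traits through
   its shared SNP node;
2. two SNPs associated with two different traits but in high LD gain a
   SNP-SNP edge;
3. two SNPs in high LD associated with the same trait gain a SNP-SNP
   edge flagged as (putative) epistasis.

Trait-trait edges never occur; trait-SNP edges carry a fixed weight and
SNP-SNP edges are weighted by r-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

TRAIT_SNP_EDGE_WEIGHT = 1.0


def pairwise_r2(g_a, g_b) -> float:
    """Squared Pearson correlation of two genotype-code vectors.

    Computed over shared non-missing samples; requires at least three and
    returns NaN (with a warning) if either column is constant.
    """
    a = np.array(g_a, dtype=float, copy=True)
    b = np.array(g_b, dtype=float, copy=True)
    a[np.asarray(g_a) == MISSING] = np.nan
    b[np.asarray(g_b) == MISSING] = np.nan
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 3:
        raise ValueError("need at least 3 shared non-missing calls")
    a, b = a[keep], b[keep]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant genotype column: r2 undefined")
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(geno: GenotypeMatrix, snp_ids=None) -> pd.DataFrame:
    """Symmetric r-squared matrix (unit diagonal) over the given SNPs."""
    idx = (
        list(range(geno.n_snps))
        if snp_ids is None
        else [geno.snp_index(s) for s in snp_ids]
    )
    ids = [str(geno.snp_id[j]) for j in idx]
    k = len(idx)
    out = np.eye(k)
    for (ia, ja), (ib, jb) in combinations(enumerate(idx), 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = pairwise_r2(geno.column(ja), geno.column(jb))
        out[ia, ib] = out[ib, ia] = r2
    return pd.DataFrame(out, index=ids, columns=ids)


def ld_window(geno: GenotypeMatrix, focal_snp: str, flank_bp: int):
    """LD matrix of all SNPs within +-flank_bp of a focal SNP (inclusive).

    Returns (LD matrix ordered by position, window marker table) for
    local Manhattan / heatmap displays.
    """
    j = geno.snp_index(focal_snp)
    c, p = geno.chrom[j], geno.pos[j]
    mask = (geno.chrom == c) & (geno.pos >= p - flank_bp) & (geno.pos <= p + flank_bp)
    idx = np.flatnonzero(mask)
    idx = idx[np.argsort(geno.pos[idx], kind="stable")]
    ids = [str(geno.snp_id[i]) for i in idx]
    mat = ld_matrix(geno, snp_ids=ids)
    info = pd.DataFrame(
        {"snp_id": ids, "chrom": geno.chrom[idx], "pos": geno.pos[idx]}
    )
    return mat, info


@dataclass
class RegionSummary:
    trait: str
    chromosome: int
    count: int
    min_pos: int
    max_pos: int

    @property
    def span_bp(self) -> int:
        return self.max_pos - self.min_pos

    @property
    def span_kb(self) -> float:
        return round(self.span_bp / 1e3, 1)

    @property
    def span_mb(self) -> float:
        return round(self.span_bp / 1e6, 1)


def region_summary(snp_records: pd.DataFrame, trait: str, chromosome: int) -> RegionSummary:
    """Cluster summary of a trait's significant SNPs on one chromosome.

    The span is max - min position in bp (the convention that reproduces
    published kb-scale cluster widths from 1-based positions).
    """
    sub = snp_records
    if "trait" in sub.columns:
        sub = sub[sub["trait"] == trait]
    sub = sub[sub["chrom"].astype(int) == int(chromosome)]
    if len(sub) == 0:
        raise ValueError(f"no records for {trait} on chromosome {chromosome}")
    pos = sub["pos"].astype(int)
    return RegionSummary(
        trait=trait,
        chromosome=int(chromosome),
        count=int(len(sub)),
        min_pos=int(pos.min()),
        max_pos=int(pos.max()),
    )


def build_network(
    trait_results: dict,
    ld: pd.DataFrame | None = None,
    r2_high: float = 0.8,
    prior_loci: dict | None = None,
) -> nx.Graph:
    """Assemble the trait-SNP association network.

    Parameters
    ----------
    trait_results : dict
        trait name -> DataFrame with columns snp_id and lod (significant
        SNPs for that trait).  ``prior_loci`` (same shape) adds loci from
        earlier studies as extra trait nodes.
    ld : DataFrame
        Symmetric r-squared matrix indexed by snp_id covering every
        listed SNP pair (missing pairs are treated as unlinked).
    r2_high : float
        Threshold above which a SNP-SNP edge is drawn.
    """
    g = nx.Graph()
    all_traits = dict(trait_results)
    classes = {t: "tolerance-index" for t in trait_results}
    for t, df in (prior_loci or {}).items():
        all_traits[t] = df
        classes[t] = "prior-study"
    snp_traits: dict[str, list] = {}
    for trait, df in all_traits.items():
        g.add_node(trait, kind="trait", trait_class=classes[trait])
        if "lod" not in df.columns:
            raise ValueError(f"SNP list for {trait!r} lacks LOD values")
        for _, row in df.iterrows():
            sid = str(row["snp_id"])
            if pd.isna(row["lod"]):
                raise ValueError(f"SNP {sid} listed without LOD")
            lod = float(row["lod"])
            if sid not in g:
                g.add_node(sid, kind="snp", lod=lod)
            else:
                g.nodes[sid]["lod"] = max(g.nodes[sid]["lod"], lod)
            g.add_edge(trait, sid, kind="trait-snp", weight=TRAIT_SNP_EDGE_WEIGHT,
                       epistasis=False)
            snp_traits.setdefault(sid, []).append(trait)
    snps = sorted(snp_traits)
    for sa, sb in combinations(snps, 2):
        r2 = np.nan
        if ld is not None and sa in ld.index and sb in ld.columns:
            r2 = float(ld.loc[sa, sb])
        if np.isnan(r2) or r2 < r2_high:
            continue
        same_trait = bool(set(snp_traits[sa]) & set(snp_traits[sb]))
        g.add_edge(sa, sb, kind="snp-snp", weight=r2, epistasis=same_trait)
    return g


def subnetworks(network: nx.Graph) -> list:
    """Connected components, largest first (deterministic order)."""
    comps = [sorted(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), c))


def export_graph(network: nx.Graph, prefix: str, formats=("graphml", "sif", "nodes")):
    """Write GraphML, a SIF edge list and a node attribute table."""
    written = {}
    if "graphml" in formats:
        path = f"{prefix}.graphml"
        nx.write_graphml(network, path)
        written["graphml"] = path
    if "sif" in formats:
        path = f"{prefix}.sif"
        with open(path, "w") as fh:
            for a, b, data in network.edges(data=True):
                fh.write(f"{a}\t{data['kind']}\t{b}\n")
        written["sif"] = path
    if "nodes" in formats:
        path = f"{prefix}.nodes.tsv"
        rows = []
        for node, data in network.nodes(data=True):
            rows.append(
                {
                    "node": node,
                    "kind": data.get("kind"),
                    "trait_class": data.get("trait_class", ""),
                    "lod": data.get("lod", ""),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["nodes"] = path
    return written
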