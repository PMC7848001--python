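"""Multi-locus GWAS via iterated fixed-effect models with pseudo-QTN covariates.

The scan alternates two fixed-effect models, in the style of the
BLINK/FarmCPU family:

* a per-marker test model — phenotype regressed on the current pseudo-QTN
  set plus the tested marker, with a two-sided t-test on the marker
  effect; when the tested marker is in high LD (r-squared above the
  pruning threshold) with a pseudo-QTN, that pseudo-QTN is dropped from
  the covariates for that single test;
* a selection model — nested prefixes of the LD-pruned, p-ordered
  candidate list are compared by BIC to choose the pseudo-QTN set.

Iteration stops when the pseudo-QTN set repeats or after
``max_iterations``.  Binary traits are recoded 0/1 and analyzed with the
same linear machinery.  Significance uses a fixed LOD (=-log10 p)
threshold with a top-N fallback when nothing passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeMatrix
from .qc import maf as snp_maf

P_FLOOR = np.finfo(float).tiny


@dataclass
class BlinkConfig:
    """Scan settings.

    ``candidate_p_cap`` gates entry to the pseudo-QTN candidate list;
    ``None`` means the Bonferroni-style default 0.01 / n_markers, which
    keeps the candidate list empty on null data so that BIC selection
    cannot absorb noise covariates.
    """

    ld_prune_r2: float = 0.7
    max_iterations: int = 10
    candidate_p_cap: float | None = None
    lod_threshold: float = 3.0
    fallback_top_n: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.ld_prune_r2 <= 1.0:
            raise ValueError("ld_prune_r2 must lie in (0, 1]")
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be positive")


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp_id, chrom, pos, effect, p, lod, maf, significant, fallback
    qtn_indices: list
    qtn_ids: list
    qtn_effects: np.ndarray
    iterations: list = field(default_factory=list)  # pseudo-QTN sets per iteration
    fallback: bool = False

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def encode_genotypes(geno) -> tuple[np.ndarray, np.ndarray]:
    """Numeric marker matrix: missing cells mean-imputed per SNP.

    Returns (matrix, testable) where ``testable`` flags polymorphic SNPs;
    monomorphic columns cannot carry association signal and are excluded
    from testing.
    """
    if isinstance(geno, GenotypeMatrix):
        calls = geno.calls
    else:
        calls = np.asarray(geno)
    M = calls.astype(float)
    M[calls == MISSING] = np.nan
    means = np.nanmean(np.where(np.isnan(M), np.nan, M), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    inds = np.where(np.isnan(M))
    M[inds] = means[inds[1]]
    testable = M.std(axis=0) > 0
    return M, testable


def _pairwise_r2_to_set(M: np.ndarray, cols: list) -> np.ndarray:
    """r-squared between every marker and each column in ``cols``."""
    n = M.shape[0]
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0)
    sd[sd == 0] = np.nan
    Q = Mc[:, cols] / sd[cols]
    Z = Mc / sd
    r = Z.T @ Q / n
    return np.nan_to_num(r**2, nan=0.0)


def fem_scan(
    M: np.ndarray,
    y: np.ndarray,
    pseudo_qtns: list,
    testable: np.ndarray | None = None,
    ld_prune_r2: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker p-values and effects under the testing fixed-effect model.

    For each marker j the phenotype is regressed on [intercept,
    pseudo-QTNs, marker j] by least squares and the marker coefficient is
    t-tested.  Pseudo-QTNs in LD with the tested marker (r-squared >=
    ``ld_prune_r2``, which covers the marker testing itself) are dropped
    from the covariates for that test.
    """
    n, m = M.shape
    y = np.asarray(y, dtype=float)
    if testable is None:
        testable = M.std(axis=0) > 0
    pseudo_qtns = list(pseudo_qtns)
    p = np.full(m, np.nan)
    d = np.full(m, np.nan)

    if pseudo_qtns:
        r2q = _pairwise_r2_to_set(M, pseudo_qtns)  # (m, k)
        conflict = r2q >= ld_prune_r2
    else:
        conflict = np.zeros((m, 0), dtype=bool)

    def scan_block(marker_idx, qtn_subset):
        if len(marker_idx) == 0:
            return
        X0 = np.column_stack([np.ones(n)] + [M[:, q] for q in qtn_subset])
        Q0, _ = np.linalg.qr(X0)
        yr = y - Q0 @ (Q0.T @ y)
        Mb = M[:, marker_idx]
        Mr = Mb - Q0 @ (Q0.T @ Mb)
        ss = (Mr**2).sum(axis=0)
        df = n - X0.shape[1] - 1
        if df <= 0:
            return
        ok = ss > n * 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (Mr * yr[:, None]).sum(axis=0) / ss
            rss = (yr**2).sum() - slope**2 * ss
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / df / ss)
            with np.errstate(over="ignore"):
                t = slope / se
        pj = 2.0 * stats.t.sf(np.abs(t), df)
        pj = np.maximum(pj, P_FLOOR)
        idx = np.asarray(marker_idx)
        p[idx[ok]] = pj[ok]
        d[idx[ok]] = slope[ok]

    test_idx = np.flatnonzero(testable)
    plain = test_idx[~conflict[test_idx].any(axis=1)] if pseudo_qtns else test_idx
    scan_block(plain, pseudo_qtns)
    if pseudo_qtns:
        special = test_idx[conflict[test_idx].any(axis=1)]
        # group markers by the exact set of pseudo-QTNs they exclude
        patterns = {}
        for j in special:
            key = tuple(np.flatnonzero(conflict[j]))
            patterns.setdefault(key, []).append(j)
        for key, markers in patterns.items():
            kept = [q for i, q in enumerate(pseudo_qtns) if i not in set(key)]
            scan_block(np.asarray(markers), kept)
    return p, d


def prune_candidates(
    p_values: np.ndarray,
    M: np.ndarray,
    config: BlinkConfig,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> list:
    """Greedy LD pruning of p-ordered association candidates.

    Markers with p below the candidate cap are scanned in ascending-p
    order (ties broken by chromosome then position for determinism); a
    marker is kept iff its r-squared with every already-kept marker is
    below ``ld_prune_r2``.
    """
    m = len(p_values)
    chrom = np.zeros(m) if chrom is None else np.asarray(chrom)
    pos = np.arange(m) if pos is None else np.asarray(pos)
    cap = config.candidate_p_cap if config.candidate_p_cap is not None else 0.01 / m
    eligible = np.flatnonzero(~np.isnan(p_values) & (p_values <= cap))
    order = eligible[np.lexsort((pos[eligible], chrom[eligible], p_values[eligible]))]
    kept: list[int] = []
    if len(order) == 0:
        return kept
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0)
    for j in order:
        ok = True
        for q in kept:
            denom = sd[j] * sd[q]
            r2 = 0.0 if denom == 0 else (Mc[:, j] @ Mc[:, q] / (M.shape[0] * denom)) ** 2
            if r2 >= config.ld_prune_r2:
                ok = False
                break
        if ok:
            kept.append(int(j))
    return kept


def select_qtn_set(
    candidates: list,
    M: np.ndarray,
    y: np.ndarray,
    config: BlinkConfig,
) -> tuple[list, np.ndarray]:
    """Choose the pseudo-QTN set by BIC over nested prefixes of the candidates.

    Fits the selection model with the top-m candidates for
    m = 0..min(len(candidates), n/10) and returns the prefix minimizing
    BIC = n ln(RSS/n) + (m+1) ln(n), together with its fitted effects.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    m_max = min(len(candidates), n // 10)
    best_bic, best_m, best_beta = np.inf, 0, np.zeros(0)
    for mm in range(m_max + 1):
        X = np.column_stack([np.ones(n)] + [M[:, q] for q in candidates[:mm]])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rss = max(rss, n * 1e-300)
        bic = n * np.log(rss / n) + (mm + 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_m, best_beta = bic, mm, beta[1:]
    return list(candidates[:best_m]), np.asarray(best_beta)


def call_significant(
    table: pd.DataFrame, lod_threshold: float = 3.0, fallback_top_n: int = 5
) -> tuple[pd.DataFrame, bool]:
    """Strict LOD > threshold rule; top-N-by-LOD fallback when nothing passes."""
    table = table.copy()
    lod = table["lod"].to_numpy()
    sig = lod > lod_threshold
    fallback = False
    if not np.any(sig) and len(table) > 0:
        fallback = True
        order = np.argsort(-np.nan_to_num(lod, nan=-np.inf), kind="stable")
        top = order[: min(fallback_top_n, int(np.isfinite(lod).sum()))]
        sig = np.zeros(len(table), dtype=bool)
        sig[top] = True
    table["significant"] = sig
    table["fallback"] = fallback
    return table, fallback


class BlinkGWAS(BaseEstimator):
    """Iterative multi-locus GWAS estimator.

    scikit-learn style: construct with the scan settings, ``fit`` a
    :class:`GenotypeMatrix` (or a coded array) against a phenotype
    vector, then read per-marker statistics off the fitted attributes.

    Attributes (after fit)
    ----------------------
    result_ : GwasResult
    pvalues_, lod_, effects_ : ndarray per marker
    qtn_ : list of pseudo-QTN marker indices
    """

    def __init__(self, ld_prune_r2=0.7, max_iterations=10, candidate_p_cap=None,
                 lod_threshold=3.0, fallback_top_n=5, seed=0):
        self.ld_prune_r2 = ld_prune_r2
        self.max_iterations = max_iterations
        self.candidate_p_cap = candidate_p_cap
        self.lod_threshold = lod_threshold
        self.fallback_top_n = fallback_top_n
        self.seed = seed

    def _config(self) -> BlinkConfig:
        return BlinkConfig(
            ld_prune_r2=self.ld_prune_r2,
            max_iterations=self.max_iterations,
            candidate_p_cap=self.candidate_p_cap,
            lod_threshold=self.lod_threshold,
            fallback_top_n=self.fallback_top_n,
            seed=self.seed,
        )

    def fit(self, X, y):
        config = self._config()
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ValueError("phenotype contains missing values; drop them first")
        uniq = np.unique(y)
        if set(uniq) <= {1.0, 9.0} and len(uniq) > 1:
            y = (y == 9.0).astype(float)  # habit-change coding -> 0/1
        if isinstance(X, GenotypeMatrix):
            geno, chrom, pos, snp_id = X, X.chrom, X.pos, X.snp_id
        else:
            arr = np.asarray(X)
            chrom = np.ones(arr.shape[1], dtype=int)
            pos = np.arange(1, arr.shape[1] + 1)
            snp_id = np.array([f"M{j}" for j in range(arr.shape[1])], dtype=object)
            geno = arr
        M, testable = encode_genotypes(geno)
        if len(y) != M.shape[0]:
            raise ValueError("phenotype length does not match samples")

        qtns: list[int] = []
        trace = []
        p = np.full(M.shape[1], np.nan)
        d = np.full(M.shape[1], np.nan)
        for _ in range(config.max_iterations):
            p, d = fem_scan(M, y, qtns, testable, config.ld_prune_r2)
            candidates = prune_candidates(p, M, config, chrom, pos)
            new_qtns, effects = select_qtn_set(candidates, M, y, config)
            trace.append(list(new_qtns))
            if set(new_qtns) == set(qtns):
                qtns = new_qtns
                break
            qtns = new_qtns
        else:
            effects = select_qtn_set(qtns, M, y, config)[1]
        p, d = fem_scan(M, y, qtns, testable, config.ld_prune_r2)
        _, qtn_effects = select_qtn_set(list(qtns), M, y, config) if qtns else ([], np.zeros(0))
        if qtns:
            # effects of the final set re-fit jointly at full length
            X2 = np.column_stack([np.ones(len(y))] + [M[:, q] for q in qtns])
            qtn_effects = np.linalg.lstsq(X2, y, rcond=None)[0][1:]

        lod = -np.log10(np.maximum(p, P_FLOOR))
        if isinstance(X, GenotypeMatrix):
            mafs = np.array([snp_maf(X.column(j)) for j in range(X.n_snps)])
        else:
            mafs = np.array([snp_maf(np.asarray(X)[:, j]) for j in range(M.shape[1])])
        table = pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": pos,
                "effect": d,
                "p": p,
                "lod": lod,
                "maf": mafs,
                "testable": testable,
            }
        )
        table, fallback = call_significant(
            table, config.lod_threshold, config.fallback_top_n
        )
        self.result_ = GwasResult(
            table=table,
            qtn_indices=list(qtns),
            qtn_ids=[str(snp_id[q]) for q in qtns],
            qtn_effects=np.asarray(qtn_effects),
            iterations=trace,
            fallback=fallback,
        )
        self.pvalues_ = p
        self.lod_ = lod
        self.effects_ = d
        self.qtn_ = list(qtns)
        return self


def blink(geno, phenotype, config: BlinkConfig | None = None) -> GwasResult:
    """Functional wrapper around :class:`BlinkGWAS`."""
    config = config or BlinkConfig()
    est = BlinkGWAS(**{f: getattr(config, f) for f in (
        "ld_prune_r2", "max_iterations", "candidate_p_cap", "lod_threshold",
        "fallback_top_n", "seed")})
    return est.fit(geno, phenotype).result_
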