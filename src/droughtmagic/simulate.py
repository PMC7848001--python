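"""Synthetic MAGIC population generator.

Emulates the structure of an eight-founder funnel-cross population of
recombinant inbred lines (RILs): inbred founders are intercrossed through
a balanced funnel (4 two-way F1s -> 2 four-way hybrids -> 1 eight-way
hybrid) and then advanced by single-seed-descent selfing.  Recombination
follows a no-interference (Haldane) model: crossover counts per
chromosome are Poisson with mean equal to the map length in Morgans and
crossover positions are uniform on the genetic map.

The default scale mirrors the cowpea study population the downstream
analysis is designed for: 8 founders, 305 F8 RILs, 11 chromosomes.
Phenotypes are simulated for five traits under two irrigation regimes
(full / restricted) so that tolerance indices, a right-skewed yield
index and a liability-threshold growth-habit-change trait can all be
derived downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

REGIMES = ("full", "restricted")
QUANT_TRAITS = ("flowering_time", "maturity", "seed_weight", "grain_yield")
TRAITS = QUANT_TRAITS + ("growth_habit",)

#: Number of ordinal growth-habit categories (acute erect .. prostrate).
N_HABIT_LEVELS = 6


class ConfigurationError(ValueError):
    """Raised for invalid simulator settings."""


@dataclass
class GeneticMap:
    """Per-SNP genetic (cM) and physical (bp) coordinates.

    ``chrom`` holds integer chromosome labels (1..n_chrom); cM positions
    are non-decreasing and bp positions strictly increasing within a
    chromosome, linked by a per-chromosome linear scaling.
    """

    chrom: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    lengths_cm: np.ndarray
    lengths_bp: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.chrom)

    @property
    def n_chrom(self) -> int:
        return len(self.lengths_cm)

    def chrom_slice(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)


@dataclass
class FounderSet:
    """Fully inbred founder parents: one binary haplotype per founder."""

    haplotypes: np.ndarray  # (n_founders, n_snps) in {0, 1}
    labels: list
    monomorphic: np.ndarray = None  # flags SNPs fixed across founders

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    seed: int
    qtl: dict = field(default_factory=dict)  # (trait, regime) -> [(snp_idx, effect)]
    heritability: dict = field(default_factory=dict)
    regime_ratio: dict = field(default_factory=dict)
    founder_origins: np.ndarray = None  # (n_rils, 2, n_snps) founder index
    habit_change_loading: float = 0.0

    def validate(self, n_snps: int) -> None:
        for (trait, regime), qtls in self.qtl.items():
            for idx, _ in qtls:
                if not 0 <= idx < n_snps:
                    raise ConfigurationError(
                        f"QTL index {idx} out of range for {trait}/{regime}"
                    )
        for h2 in self.heritability.values():
            if not 0.0 <= h2 <= 1.0:
                raise ConfigurationError("heritability must lie in [0, 1]")


def make_genetic_map(
    n_chrom: int = 11,
    cm_lengths=80.0,
    snps_per_chrom=182,
    bp_per_cm: float = 250_000.0,
    seed: int = 0,
) -> GeneticMap:
    """Draw a random marker map: uniform cM placement, linear cM->bp scaling."""
    if n_chrom < 1:
        raise ConfigurationError("n_chrom must be >= 1")
    cm_lengths = np.broadcast_to(np.atleast_1d(np.asarray(cm_lengths, float)), (n_chrom,))
    snps_per_chrom = np.broadcast_to(
        np.atleast_1d(np.asarray(snps_per_chrom, int)), (n_chrom,)
    )
    if (cm_lengths <= 0).any() or bp_per_cm <= 0:
        raise ConfigurationError("map lengths must be positive")
    if (snps_per_chrom < 1).any():
        raise ConfigurationError("need at least one SNP per chromosome")
    rng = np.random.default_rng(seed)
    chrom, cm, bp = [], [], []
    for c in range(n_chrom):
        pos_cm = np.sort(rng.uniform(0.0, cm_lengths[c], size=snps_per_chrom[c]))
        pos_bp = np.floor(pos_cm * bp_per_cm).astype(np.int64) + 1
        # enforce strictly increasing physical positions after rounding
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(len(pos_bp)))
        chrom.append(np.full(snps_per_chrom[c], c + 1))
        cm.append(pos_cm)
        bp.append(pos_bp)
    return GeneticMap(
        chrom=np.concatenate(chrom),
        cm=np.concatenate(cm),
        bp=np.concatenate(bp),
        lengths_cm=cm_lengths.copy(),
        lengths_bp=np.floor(cm_lengths * bp_per_cm).astype(np.int64),
    )


def simulate_founders(
    gmap: GeneticMap,
    n_founders: int = 8,
    maf_distribution=None,
    seed: int = 0,
    max_retries: int = 10,
) -> FounderSet:
    """Draw homozygous founder haplotypes.

    Per SNP an allele frequency is drawn from ``maf_distribution`` (a
    callable ``f(rng) -> frequency``; default Uniform(0.15, 0.85)) and
    each founder's allele is Bernoulli at that frequency.  SNPs that come
    out fixed across all founders are re-drawn up to ``max_retries``
    times, then flagged monomorphic.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least two founders")
    rng = np.random.default_rng(seed)
    if maf_distribution is None:
        maf_distribution = lambda r: r.uniform(0.15, 0.85)
    m = gmap.n_snps
    haps = np.empty((n_founders, m), dtype=np.int8)
    mono = np.zeros(m, dtype=bool)
    for j in range(m):
        for _ in range(max_retries + 1):
            q = maf_distribution(rng)
            col = (rng.random(n_founders) < q).astype(np.int8)
            if 0 < col.sum() < n_founders:
                break
        else:
            mono[j] = True
        haps[:, j] = col
    labels = [f"P{i + 1}" for i in range(n_founders)]
    return FounderSet(haplotypes=haps, labels=labels, monomorphic=mono)


def _meiosis(origins_a, origins_b, gmap: GeneticMap, rng) -> np.ndarray:
    """One gamete from a diploid of two founder-origin haplotypes.

    Haldane model: per chromosome, Poisson(L Morgans) crossovers placed
    uniformly in cM; the starting haplotype is chosen at random.
    """
    gamete = np.empty_like(origins_a)
    for c in range(gmap.n_chrom):
        idx = gmap.chrom_slice(c + 1)
        length_cm = gmap.lengths_cm[c]
        n_x = rng.poisson(length_cm / 100.0)
        phase0 = rng.integers(2)
        if n_x == 0:
            phase = np.full(len(idx), phase0)
        else:
            xo = np.sort(rng.uniform(0.0, length_cm, size=n_x))
            phase = (phase0 + np.searchsorted(xo, gmap.cm[idx])) % 2
        gamete[idx] = np.where(phase == 0, origins_a[idx], origins_b[idx])
    return gamete


def funnel_cross(
    founders: FounderSet,
    gmap: GeneticMap,
    n_rils: int = 305,
    selfing_generations: int = 7,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Advance a balanced funnel cross to inbred lines.

    Each RIL descends from its own randomly permuted funnel (balancing
    founder contributions) and then ``selfing_generations`` rounds of
    single-seed descent from the eight-way F1 (7 rounds gives F8 lines).
    Returns genotypes coded 0/1/2 from the two gametes per RIL plus the
    founder-origin mosaic as simulation truth.
    """
    nf = founders.n_founders
    if nf < 2 or (nf & (nf - 1)) != 0:
        raise ConfigurationError("funnel layout needs a power-of-two founder count")
    if selfing_generations < 0:
        raise ConfigurationError("selfing_generations must be >= 0")
    rng = np.random.default_rng(seed)
    m = gmap.n_snps
    calls = np.empty((n_rils, m), dtype=np.int8)
    origins = np.empty((n_rils, 2, m), dtype=np.uint8)
    base = np.arange(m)
    for i in range(n_rils):
        order = rng.permutation(nf)
        # level 0: founders as (hapA, hapB) pairs of origin indices
        layer = [
            (np.full(m, f, dtype=np.uint8), np.full(m, f, dtype=np.uint8))
            for f in order
        ]
        while len(layer) > 1:
            nxt = []
            for a, b in zip(layer[::2], layer[1::2]):
                nxt.append((_meiosis(*a, gmap, rng), _meiosis(*b, gmap, rng)))
            layer = nxt
        ind = layer[0]
        for _ in range(selfing_generations):
            ind = (_meiosis(*ind, gmap, rng), _meiosis(*ind, gmap, rng))
        origins[i, 0], origins[i, 1] = ind
        a1 = founders.haplotypes[ind[0], base]
        a2 = founders.haplotypes[ind[1], base]
        calls[i] = a1 + a2
    snp_id = np.array(
        [f"S{c}_{p}" for c, p in zip(gmap.chrom, gmap.bp)], dtype=object
    )
    geno = GenotypeMatrix(calls=calls, snp_id=snp_id, chrom=gmap.chrom, pos=gmap.bp)
    truth = SimTruth(seed=seed, founder_origins=origins)
    return geno, truth


def inject_artifacts(
    geno: GenotypeMatrix,
    missing_rate: float = 0.0,
    het_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Add missing calls and spurious heterozygote errors for QC to remove."""
    for r in (missing_rate, het_error_rate):
        if not 0.0 <= r < 1.0:
            raise ConfigurationError("artifact rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = geno.calls.copy()
    hom = (calls == 0) | (calls == 2)
    flip = hom & (rng.random(calls.shape) < het_error_rate)
    calls[flip] = 1
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = MISSING
    out = GenotypeMatrix(
        calls=calls,
        snp_id=geno.snp_id.copy(),
        chrom=geno.chrom.copy(),
        pos=geno.pos.copy(),
        samples=list(geno.samples),
    )
    report = {
        "n_set_missing": int(miss.sum()),
        "n_het_flipped": int((flip & ~miss).sum()),
    }
    return out, report


@dataclass
class TraitSpec:
    """Architecture of one quantitative trait under the two regimes.

    ``qtl`` lists (snp_index, effect_full, effect_restricted) additive
    allele-substitution effects; a regime difference in effects is what
    gives the tolerance index genetic variance.  ``cv`` is the residual
    coefficient of variation per regime (for the multiplicative yield
    trait it is the residual log-scale standard deviation).
    """

    mean_full: float
    regime_ratio: float
    cv: float
    qtl: list = field(default_factory=list)
    multiplicative: bool = False


@dataclass
class PhenotypeArchitecture:
    traits: dict  # trait name -> TraitSpec (quantitative traits)
    habit_qtl: list = field(default_factory=list)  # (snp_idx, latent effect)
    habit_noise_sd: float = 1.0
    habit_change_loading: float = 0.35
    habit_change_rate: float = 154.0 / 305.0


def default_architecture(n_snps: int, seed: int = 0, n_qtl: int = 3) -> PhenotypeArchitecture:
    """Study-scale defaults.

    Trait means/ratios and dispersions emulate the magnitudes the index
    analysis expects: maturity and flowering indices near 100 with
    modest spread, a seed-weight index above 100, and a strongly
    right-skewed yield index well below 100 (yield is hit hardest by
    restricted irrigation).  Each trait carries a few additive QTLs with
    regime-specific effects so indices are heritable.
    """
    rng = np.random.default_rng(seed)
    specs = {
        # mean_full, restricted/full ratio, per-regime residual CV (log-sd for yield)
        "flowering_time": (45.0, 0.9748, 0.035),
        "maturity": (60.0, 1.0474, 0.095),
        "seed_weight": (20.0, 1.1309, 0.100),
        "grain_yield": (2000.0, 0.26, 0.62),
    }
    traits = {}
    for name, (mean, ratio, cv) in specs.items():
        idx = rng.choice(n_snps, size=min(n_qtl, n_snps), replace=False)
        mult = name == "grain_yield"
        qtl = []
        for j in idx:
            if mult:
                e_full = rng.normal(0.0, 0.10)
                e_res = e_full + rng.normal(0.0, 0.15)
            else:
                e_full = rng.normal(0.0, 0.02) * mean
                e_res = e_full + rng.normal(0.0, 0.03) * mean
            qtl.append((int(j), float(e_full), float(e_res)))
        traits[name] = TraitSpec(
            mean_full=mean, regime_ratio=ratio, cv=cv, qtl=qtl, multiplicative=mult
        )
    habit_qtl = [
        (int(j), float(rng.normal(0.0, 0.4)))
        for j in rng.choice(n_snps, size=min(n_qtl, n_snps), replace=False)
    ]
    return PhenotypeArchitecture(traits=traits, habit_qtl=habit_qtl)


def _habit_scores(latent: np.ndarray) -> np.ndarray:
    """Ordinal 1..6 scores at equal-probability cut points of N(0, 1)."""
    cuts = stats.norm.ppf(np.arange(1, N_HABIT_LEVELS) / N_HABIT_LEVELS)
    return (np.searchsorted(cuts, latent) + 1).astype(np.int64)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    architecture: PhenotypeArchitecture | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-regime phenotypes for the five traits.

    Quantitative traits are ``mean * (1 + genetic) + residual`` per
    regime; grain yield is multiplicative with log-normal residuals so
    its tolerance index is right-skewed.  Growth habit is an ordinal 1-6
    score from a latent Gaussian; habit *change* is a liability-threshold
    binary trait whose liability loads on the standardized yield-index
    latent, so a positive loading makes habit change more likely in
    lines whose yield index is high.

    Returns a long-format table (one row per RIL x regime) and the
    simulation truth.
    """
    n = geno.n_samples
    if architecture is None:
        architecture = default_architecture(geno.n_snps, seed=seed)
    rng = np.random.default_rng(seed)
    dose = geno.calls.astype(float)
    dose[geno.calls == MISSING] = np.nan
    # centered dosage; missing treated as the SNP mean (dose 1 fallback)
    col_mean = np.nanmean(np.where(np.isnan(dose), np.nan, dose), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    dose = np.where(np.isnan(dose), col_mean[None, :], dose) - col_mean[None, :]

    truth = SimTruth(
        seed=seed, habit_change_loading=architecture.habit_change_loading
    )
    values = {regime: {} for regime in REGIMES}
    for name, spec in architecture.traits.items():
        for q, *_ in spec.qtl:
            if not 0 <= q < geno.n_snps:
                raise ConfigurationError(f"QTL index {q} out of range for {name}")
        for regime in REGIMES:
            mean = spec.mean_full * (spec.regime_ratio if regime == "restricted" else 1.0)
            g = np.zeros(n)
            effects = []
            for j, e_full, e_res in spec.qtl:
                e = e_res if regime == "restricted" else e_full
                g += e * dose[:, j]
                effects.append((j, e))
            truth.qtl[(name, regime)] = effects
            truth.regime_ratio[name] = spec.regime_ratio
            if spec.multiplicative:
                y = mean * np.exp(g + rng.normal(0.0, spec.cv, size=n))
            else:
                y = mean * (1.0 + g / max(spec.mean_full, 1e-12)) + rng.normal(
                    0.0, spec.cv * mean, size=n
                )
            values[regime][name] = y

    # growth habit: shared latent per line, regime scores + liability change
    habit_gen = np.zeros(n)
    for j, e in architecture.habit_qtl:
        if not 0 <= j < geno.n_snps:
            raise ConfigurationError(f"habit QTL index {j} out of range")
        habit_gen += e * dose[:, j]
    truth.qtl[("growth_habit", "full")] = list(architecture.habit_qtl)
    lat = habit_gen + rng.normal(0.0, architecture.habit_noise_sd, size=n)
    lat = (lat - lat.mean()) / max(lat.std(), 1e-12)
    full_score = _habit_scores(lat)

    log_ratio = np.log(values["restricted"]["grain_yield"]) - np.log(
        values["full"]["grain_yield"]
    )
    z_yield = (log_ratio - log_ratio.mean()) / max(log_ratio.std(), 1e-12)
    lam = architecture.habit_change_loading
    liability = lam * z_yield + np.sqrt(max(1.0 - lam**2, 0.0)) * rng.normal(size=n)
    tau = stats.norm.ppf(1.0 - architecture.habit_change_rate)
    changed = liability > tau
    restricted_score = full_score.copy()
    # changed lines shift one category toward erect habits (score 1 wraps up)
    restricted_score[changed] = np.where(
        full_score[changed] > 1, full_score[changed] - 1, full_score[changed] + 1
    )
    values["full"]["growth_habit"] = full_score
    values["restricted"]["growth_habit"] = restricted_score

    rows = []
    for regime in REGIMES:
        df = pd.DataFrame({"ril": geno.samples, "regime": regime})
        for name in TRAITS:
            df[name] = values[regime][name]
        rows.append(df)
    pheno = pd.concat(rows, ignore_index=True)
    truth.validate(geno.n_snps)
    return pheno, truth


def simulate_population(
    n_rils: int = 305,
    n_chrom: int = 11,
    snps_per_chrom: int = 182,
    cm_lengths=80.0,
    selfing_generations: int = 7,
    missing_rate: float = 0.0,
    het_error_rate: float = 0.0,
    architecture: PhenotypeArchitecture | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Convenience wrapper: map -> founders -> funnel -> phenotypes."""
    rng = np.random.default_rng(seed)
    s_map, s_fnd, s_cross, s_art, s_phen = rng.integers(2**31 - 1, size=5)
    gmap = make_genetic_map(
        n_chrom=n_chrom, cm_lengths=cm_lengths, snps_per_chrom=snps_per_chrom, seed=s_map
    )
    founders = simulate_founders(gmap, seed=s_fnd)
    geno, truth = funnel_cross(
        founders, gmap, n_rils=n_rils, selfing_generations=selfing_generations, seed=s_cross
    )
    if missing_rate or het_error_rate:
        geno, _ = inject_artifacts(
            geno, missing_rate=missing_rate, het_error_rate=het_error_rate, seed=s_art
        )
    pheno, ptruth = simulate_phenotypes(geno, architecture=architecture, seed=s_phen)
    ptruth.founder_origins = truth.founder_origins
    ptruth.seed = seed
    return geno, pheno, ptruth
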