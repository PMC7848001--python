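# Methods

This note documents the models implemented in `droughtmagic`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions that affect results.

## MAGIC population simulator (`simulate`)

**Crossing design.** Eight fully inbred founders are combined through a
balanced funnel — four two-way F1s, two four-way hybrids, one eight-way
hybrid — followed by single-seed-descent selfing (7 generations gives F8
lines, the default). Each RIL receives its own random permutation of the
founders into funnel positions, which balances founder contributions in
expectation (each ≈ 1/8) without modelling shared funnel families.

**Recombination.** Haldane model: crossover counts per chromosome are
Poisson with mean equal to the map length in Morgans, positions uniform
on the genetic map, no interference and no sex differences. This is the
simplest process consistent with a funnel-cross design when nothing more
specific is known about the organism's recombination landscape.

**Maps and markers.** Default map: 11 chromosomes of 80 cM with 182 SNPs
each (2,002 markers total — a deliberate ~16× thinning of a ~32k array so
that the full pipeline runs in seconds; the array scale is available by
configuration). Physical positions follow a per-chromosome linear scaling
of 250 kb/cM, giving bp coordinates of the magnitude seen on real cowpea
chromosomes. Founder alleles are Bernoulli draws at a per-SNP frequency
from Uniform(0.15, 0.85), so post-intercross minor allele frequencies
populate the QC-passing range; SNPs fixed across founders after a bounded
number of redraws are flagged monomorphic.

**Phenotypes.** Five traits under two regimes. Quantitative traits are
`mean × (1 + genetic) + residual` per regime with a handful of additive
QTLs whose effects differ between regimes — the regime-by-genotype
difference is what makes the tolerance index heritable. Grain yield is
multiplicative with log-normal residuals, so its tolerance index (a ratio
of log-normals) is right-skewed. Default means, restricted/full ratios
and dispersions were set once to emulate the magnitudes reported for
drought-stressed cowpea index traits (maturity index ≈ 105 ± 16,
flowering ≈ 97 ± 5, seed weight ≈ 113 ± 18, yield ≈ 42 with sd larger
than the mean and strong right skew).

**Growth habit and habit change.** Growth habit is an ordinal 1–6 score
obtained by cutting a latent Gaussian at equal-probability points (no
distribution for the category frequencies being otherwise known). Habit
*change* is a liability-threshold binary trait: liability
`λ·z_yield + √(1−λ²)·ε` with default loading λ = 0.35 on the standardized
log yield-index latent and a threshold set for a ≈ 50% change rate
(154/305 lines). A positive loading makes change monotonically more
likely with the yield index, so the downstream logistic regression
recovers a positive, significant slope in most simulated populations —
the direction observed in the motivating study. Lines that change shift
one ordinal category (downward, i.e. toward erect habits, wrapping at the
bottom); the liability construction, not the category mechanics, carries
the statistical signal.

**What the simulator does not emulate.** Field spatial effects,
year/location blocks, selection during inbreeding, genotyping batch
effects, segregation distortion, and crossover interference. Passing
tests on simulated data therefore demonstrate correctness of the
estimators under a clean additive model, not robustness to those
real-data features.

## Tolerance indices and association screening (`tolerance`)

Indices are `100 × restricted/full` per RIL; if replicate environment
rows are supplied they are averaged within regime before the ratio (the
combination rule across sites/years is a package default, not a
published procedure). The index is missing when either input is missing
or the full-irrigation value is ≤ 0. Habit change keeps the 1/9 coding
in files but is remapped to 0/1 for modelling, since 1/9 as numeric
levels would distort a regression. Summaries use the n−1 standard
deviation and bias-corrected skewness; correlations are pairwise-complete
Pearson. The logistic fit uses the statsmodels binomial GLM (IRLS), with
Wald Z = β̂/SE and a two-sided normal p-value, matching the convention of
reporting Z statistics for this screen; likelihood-ratio tests are not
used. Single-class responses and (quasi-)separated fits — detected by
non-convergence or exploding standard errors — are flagged and report no
p-value. The stored deviance path excludes the optimizer's two
initialization entries, which are not deviances of model-constrained
fits; across actual IRLS iterations the deviance is non-increasing.

## SNP quality control (`qc`)

A SNP is retained iff missing fraction < 0.10 AND heterozygosity < 0.10
AND MAF > 0.05, with *strict* inequalities: a SNP at exactly 10% missing
is removed. Heterozygosity is a per-SNP fraction across samples (the
retention filter); per-sample heterozygosity is reported for diagnostics
but never filtered on. Filtering is idempotent, and removal counts per
criterion (with overlaps) reconcile to the input SNP count. The filter is
exposed as a scikit-learn transformer (`SnpQC`), so it composes with
pipelines.

## Multi-locus GWAS (`gwas`)

The scan iterates { marker test → LD pruning → BIC set selection } until
the pseudo-QTN set repeats, with a default cap of 10 iterations (an
oscillating set stops at the cap with the trace recorded).

* **Marker test.** Least squares of the phenotype on [intercept,
  pseudo-QTNs, marker j], two-sided t-test on the marker coefficient,
  computed for all markers at once via a QR-based projection. If marker j
  is itself a pseudo-QTN or has r² ≥ 0.7 with one, that pseudo-QTN is
  dropped from the covariates for that single test; markers sharing an
  exclusion pattern are scanned together. This prevents a marker from
  being conditioned on itself or on a proxy of itself.
* **Candidate gating.** Markers enter the candidate list only below a
  p-value cap, default 0.01/m (Bonferroni-style, following the practice
  of the published multi-locus scanners). The gate matters: without it,
  BIC prefix selection absorbs the best-ranked noise markers (any marker
  with t² > ln n lowers BIC), deflates the residual variance and inflates
  every other test. With the gate, null data keep the pseudo-QTN set
  empty and per-marker p-values uniform — the LOD>3 call rate on no-QTL
  simulations sits at ~10⁻³ per marker.
* **Set selection.** Candidates are LD-pruned greedily in ascending-p
  order (ties broken by chromosome, then position, for determinism) at
  r² < 0.7, then nested prefixes are scored by
  BIC = n·ln(RSS/n) + (m+1)·ln(n), with the prefix length capped at n/10
  to avoid saturated models.
* **Binary traits** (habit change) are recoded 0/1 and analyzed with the
  same linear machinery — an approximation that mirrors how the published
  analyses ran one tool across all traits.
* **Significance** is strict LOD > 3; when nothing qualifies the top 5
  markers by LOD are reported with an explicit fallback flag, mirroring
  how below-threshold scans are conventionally reported. No kinship or
  structure covariates are used anywhere (the fixed-effect models contain
  none), and no FDR correction is applied on top of the fixed LOD rule.
* p-values are floored at the smallest positive double so LOD stays
  finite; untestable (monomorphic) markers carry missing p-values.

## LD and association networks (`ld`)

r² is the squared Pearson correlation of 0/1/2 genotype codes over
shared non-missing samples (composite LD). In RILs that are ~99%
homozygous this essentially coincides with haplotype r²; no phasing is
attempted. At least 3 shared calls are required, and constant columns
give a missing value with a warning.

Region summaries report SNP count and max−min bp span per trait and
chromosome (max−min, not +1 — the convention that reproduces published
kb-scale cluster widths from 1-based positions). Window extraction around
a focal SNP is inclusive at both boundaries.

The network builder applies three formation rules: shared SNPs join
traits; cross-trait SNP pairs in high LD gain an edge; same-trait pairs
in high LD gain an edge flagged as putative epistasis (a labelling rule,
not a statistical interaction test). The high-LD threshold defaults to
r² ≥ 0.8 — a conventional strong-LD cut-off, configurable, and the
component count is provably non-increasing as the threshold drops, which
lets users audit sensitivity. Trait–SNP edges carry a fixed weight of
1.0; SNP nodes carry their LOD as a size attribute. Graphs export to
GraphML, SIF and a node-attribute table; no layout or styling is
computed.

## Genomic selection (`gselect`)

The incidence matrix W is the identity (one record per line after regime
aggregation), so Z = WG reduces to the centered, mean-imputed marker
matrix. REML works in the kernel rotation: with the intercept projected
out and K = ZZᵀ eigendecomposed, the restricted likelihood is a function
of the single ratio δ = σ²e/σ²β, optimized by a 60-point log-grid plus
bounded refinement over δ ∈ [10⁻⁶, 10⁸]. The zero eigenspace of the
projected kernel is handled explicitly (its quadratic form is
basis-invariant), which keeps the estimator exact when markers are fewer
than samples or lines are duplicated. Zero genetic signal drives δ to the
cap (10⁸) with a warning. Marker effects solve (ZᵀZ + Iλ)β̂ = Zᵀy, computed through
the n×n kernel identity β̂ = Zᵀ(ZZᵀ + Iλ)⁻¹y when m > n; the two forms
agree to machine precision and are cross-checked in tests against a dense
solve.

Cross-validation draws a fresh seeded partition per replication into k
folds as even as possible (n mod k folds of size ⌈n/k⌉). The largest fold
is held out as the representative test set; on 249 lines this reproduces
the train/test sizes 166/83 … 217/32 for k = 3..8. At k = 2 the two folds
are 125/124 and either can serve as test; this package holds out the
larger (124 train / 125 test), whereas published two-fold splits are
sometimes reported the other way round — the difference is one line.
Variance components and column means are re-estimated within each
training fold (leakage-safe; whether published analyses re-estimated per
fold is typically unstated). A constant held-out phenotype yields a
missing accuracy for that replication. Binary habit change is predicted
on its 0/1 recode with the same linear model.

**Null calibration caveat.** Averaging accuracy over many replications on
a *single* noise phenotype does not converge to zero with the nominal
standard error, because replications share that phenotype and are
correlated. Calibration checks therefore redraw the phenotype per
replication.

## Orchestration and formats (`pipeline`, `io`, `cli`)

Coordinates are 1-based bp throughout; chromosome labels are normalized
to integers (`Vu01` → 1). The tabular genotype dialect is
`snp_id chrom pos <sample…>` with 0/1/2/NA codes; VCF input maps diploid
GT fields (0/0→0, 0/1→1, 1/1→2, missing→NA) and skips non-biallelic
records with a count. All randomness flows from one root seed split per
stage and logged in the run manifest; a rerun with the same configuration
is byte-identical. A stage failure aborts with the stage name and leaves
prior outputs on disk.

## Problem sizes

The default population is 305 RILs × 2,002 SNPs, the scale at which the
whole pipeline and its validation suite run in seconds to a few minutes;
the test suite uses smaller populations (60–300 lines, 60–500 markers)
where the property under test permits, and the acceptance script uses 10
null GWAS populations, 20 planted-QTL scans, 20 REML recoveries and 100
independent noise replications for genomic selection.

## Known limitations

* The GWAS is a fixed-effect approximation of the published BLINK design:
  no kinship, no Bayesian information beyond BIC, binary traits treated
  as quantitative.
* Composite (genotype-code) LD, not haplotype LD.
* The simulator's trait architectures are additive with log-normal or
  Gaussian noise; no epistasis is simulated even though the network
  module labels high-LD same-trait pairs as putative epistasis.
* The logistic screen is univariate by design; no multivariate or
  mixed-model alternative is provided.
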