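# droughtmagic

Drought-tolerance-index analysis for multi-parent advanced generation
intercross (MAGIC) populations: tolerance-index phenotyping, multi-locus
GWAS, LD-based association networks and rrBLUP genomic selection, together
with a funnel-cross population simulator that provides realistic inputs and
ground truth for validating every step.

## Who this is for

Plant breeders and quantitative geneticists who score traits under two
irrigation regimes (full vs restricted) in an inbred multi-parent
population — the motivating case is a cowpea (*Vigna unguiculata*) MAGIC
population of 305 F8 recombinant inbred lines (RILs) from 8 founders,
genotyped at ~32k SNPs on 11 chromosomes — and want to map and predict
drought tolerance rather than the raw traits.

## The statistics at the core

**Tolerance index.** For each trait (flowering time, maturity, 100-seed
weight, grain yield):

    TI = 100 × (Y_restricted / Y_full)

TI < 100 means drought reduced the trait. Growth habit (ordinal 1–6) is
compared between regimes and coded 1 (no change) / 9 (change); the
association of habit change with each index is tested with a univariate
logistic regression log[π/(1−π)] = β₀ + βᵢxᵢ (Wald Z).

**Multi-locus GWAS.** A BLINK-style iteration of two fixed-effect models:
a per-marker test `y = Σₖ Mₖbₖ + Mⱼdⱼ + e` conditioned on the current
pseudo-QTN set (with pseudo-QTNs in LD r² ≥ 0.7 with the tested marker
dropped for that test), and a selection model whose nested candidate
prefixes are compared by BIC. Candidates are LD-pruned in ascending-p
order and gated at a Bonferroni-style cap (0.01/m). Significance is a
strict LOD = −log₁₀(p) > 3 rule with a top-5-by-LOD fallback when no
marker passes.

**Association network.** Trait and SNP nodes; a SNP shared by two traits
joins them; SNP–SNP edges appear when pairwise LD r² ≥ 0.8 (same-trait
pairs flagged as putative epistasis); never trait–trait edges. Connected
components are the reported subnetworks.

**Genomic selection.** rrBLUP, `y = WGβ + ε` with β ~ N(0, Iσ²β), solved as
β̂ = (ZᵀZ + Iλ)⁻¹Zᵀy with Z the centered marker matrix and λ = σ²e/σ²β
estimated by REML (eigendecomposition + 1-D optimization). Accuracy is
the Pearson correlation between GEBVs and observed phenotypes in held-out
folds of a seeded k-fold cross-validation (k = 2..8, replicated).

## Worked example

```python
import droughtmagic as dm

# 8 founders -> 305 F8 RILs on 11 chromosomes, two-regime phenotypes
geno, pheno, truth = dm.simulate_population(seed=42, missing_rate=0.02,
                                            het_error_rate=0.01)
ti = dm.tolerance_table(pheno)
print(dm.summarize(ti["TI_yield"]))
filtered, report = dm.qc_filter(geno)          # missing<10%, het<10%, MAF>5%
res = dm.blink(filtered, ti["TI_yield"].to_numpy())
gs = dm.cross_validate(filtered, ti["TI_yield"].to_numpy(),
                       k_values=[5], reps=10, seed=1)
print(gs.summary())
```

prints (seed 42):

```
yield index: {'n': 305, 'min': 1.68, 'max': 249.52, 'mean': 34.23, 'sd': 34.54, 'skewness': 2.58}
QC retained: 2002 of 2002 SNPs
significant SNPs: 4  fallback: False
 k  mean_accuracy  sd_accuracy  n_reps
 5          0.063        0.084      10
```

The yield tolerance index is strongly right-skewed (drought hits yield
hardest), the scan finds a handful of LOD>3 markers in the LD
neighbourhood of the simulated drought-response loci, and the
cross-validated prediction accuracy for this low-heritability ratio trait
is low — the qualitative picture expected for drought-stressed grain
yield. A command-line interface mirrors the library
(`droughtmagic simulate | index | qc | gwas | ld | network | gs | run-all |
fixtures`); `run-all` executes the whole pipeline from one seed and writes
a manifest.

The package also ships transcriptions of the published significant-SNP
tables for the cowpea study (`dm.load_fixture("table1")`, `"table2"`),
used by the region-summary and network tooling.

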