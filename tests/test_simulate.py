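import numpy as np
import pytest
from scipy import stats

import droughtmagic as dm
from droughtmagic.simulate import (
    ConfigurationError,
    _meiosis,
    default_architecture,
)


class TestGeneticMap:
    def test_locus_bookkeeping(self):
        gmap = dm.make_genetic_map(n_chrom=11, cm_lengths=80, snps_per_chrom=20, seed=1)
        assert gmap.n_snps == 220
        assert gmap.n_chrom == 11
        for c in range(1, 12):
            idx = gmap.chrom_slice(c)
            assert len(idx) == 20
            assert (np.diff(gmap.cm[idx]) >= 0).all()
            assert (np.diff(gmap.bp[idx]) > 0).all()

    def test_degenerate_single_locus(self):
        gmap = dm.make_genetic_map(n_chrom=1, cm_lengths=10, snps_per_chrom=1, seed=0)
        assert gmap.n_snps == 1
        assert gmap.bp[0] > 0

    def test_determinism(self):
        a = dm.make_genetic_map(seed=42, snps_per_chrom=15)
        b = dm.make_genetic_map(seed=42, snps_per_chrom=15)
        assert np.array_equal(a.cm, b.cm) and np.array_equal(a.bp, b.bp)

    @pytest.mark.parametrize("kwargs", [
        {"cm_lengths": -5}, {"n_chrom": 0}, {"snps_per_chrom": 0},
        {"bp_per_cm": 0},
    ])
    def test_invalid_configuration(self, kwargs):
        with pytest.raises(ConfigurationError):
            dm.make_genetic_map(**kwargs)


class TestFounders:
    def test_deterministic_and_binary(self):
        gmap = dm.make_genetic_map(n_chrom=2, snps_per_chrom=30, seed=3)
        a = dm.simulate_founders(gmap, seed=9)
        b = dm.simulate_founders(gmap, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert set(np.unique(a.haplotypes)) <= {0, 1}
        assert a.n_founders == 8

    def test_monomorphic_founders_give_monomorphic_rils(self):
        gmap = dm.make_genetic_map(n_chrom=1, snps_per_chrom=10, seed=0)
        founders = dm.simulate_founders(gmap, seed=1)
        founders.haplotypes[:, 0] = 1  # identical at SNP 0 in all founders
        geno, _ = dm.funnel_cross(founders, gmap, n_rils=40, seed=2)
        assert (geno.calls[:, 0] == 2).all()

    def test_balanced_founder_frequency_propagates(self):
        gmap = dm.make_genetic_map(n_chrom=1, snps_per_chrom=5, seed=0)
        founders = dm.simulate_founders(gmap, seed=1)
        founders.haplotypes[:, 2] = [0, 0, 0, 0, 1, 1, 1, 1]
        geno, _ = dm.funnel_cross(founders, gmap, n_rils=400, seed=3)
        freq = geno.calls[:, 2].mean() / 2.0
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 400)

    def test_too_few_founders_rejected(self):
        gmap = dm.make_genetic_map(n_chrom=1, snps_per_chrom=5, seed=0)
        with pytest.raises(ConfigurationError):
            dm.simulate_founders(gmap, n_founders=1)


class TestFunnelCross:
    def test_row_count_and_coding(self, clean_pop):
        geno, _, _ = clean_pop
        assert geno.n_samples == 120
        assert set(np.unique(geno.calls)) <= {0, 1, 2}

    def test_non_power_of_two_founders_rejected(self):
        gmap = dm.make_genetic_map(n_chrom=1, snps_per_chrom=5, seed=0)
        founders = dm.simulate_founders(gmap, n_founders=6, seed=1)
        with pytest.raises(ConfigurationError):
            dm.funnel_cross(founders, gmap, n_rils=10)

    def test_mendelian_consistency_via_origins(self):
        """Every RIL allele equals the recorded founder's allele at that locus."""
        gmap = dm.make_genetic_map(n_chrom=2, snps_per_chrom=25, seed=4)
        founders = dm.simulate_founders(gmap, seed=5)
        geno, truth = dm.funnel_cross(founders, gmap, n_rils=30, seed=6)
        loci = np.arange(gmap.n_snps)
        for i in range(30):
            a1 = founders.haplotypes[truth.founder_origins[i, 0], loci]
            a2 = founders.haplotypes[truth.founder_origins[i, 1], loci]
            assert np.array_equal(geno.calls[i], a1 + a2)

    def test_heterozygosity_halves_per_selfing_generation(self):
        """Residual heterozygosity after g selfings is ~(1/2)^g of the F1 level."""
        gmap = dm.make_genetic_map(n_chrom=3, cm_lengths=80, snps_per_chrom=80, seed=8)
        founders = dm.simulate_founders(gmap, seed=8)
        f1, _ = dm.funnel_cross(founders, gmap, n_rils=305, selfing_generations=0, seed=9)
        f8, _ = dm.funnel_cross(founders, gmap, n_rils=305, selfing_generations=7, seed=10)
        h0 = (f1.calls == 1).mean(axis=1)  # per-RIL heterozygosity
        h7 = (f8.calls == 1).mean(axis=1)
        expected = h0.mean() / 2**7
        se = np.sqrt(h7.var(ddof=1) / len(h7) + (h0.var(ddof=1) / len(h0)) / 128**2)
        assert abs(h7.mean() - expected) < 3 * max(se, 1e-4)

    def test_founder_contributions_balanced(self):
        gmap = dm.make_genetic_map(n_chrom=2, cm_lengths=60, snps_per_chrom=50, seed=2)
        founders = dm.simulate_founders(gmap, seed=2)
        _, truth = dm.funnel_cross(founders, gmap, n_rils=300, seed=3)
        per_ril = np.stack(
            [(truth.founder_origins == f).mean(axis=(1, 2)) for f in range(8)],
            axis=1,
        )
        shares = per_ril.mean(axis=0)
        se = per_ril.std(axis=0, ddof=1) / np.sqrt(per_ril.shape[0])
        assert abs(shares.sum() - 1.0) < 1e-12
        # symmetry: each founder's mean share compatible with 1/8
        assert np.all(np.abs(shares - 0.125) < 4 * se)

    def test_crossover_count_matches_map_length(self):
        """Phase switches per meiosis average the map length in Morgans."""
        gmap = dm.make_genetic_map(n_chrom=1, cm_lengths=150, snps_per_chrom=400, seed=1)
        rng = np.random.default_rng(0)
        a = np.zeros(gmap.n_snps, dtype=np.uint8)
        b = np.ones(gmap.n_snps, dtype=np.uint8)
        switches = [
            (np.diff(_meiosis(a, b, gmap, rng)) != 0).sum() for _ in range(1000)
        ]
        mean = np.mean(switches)
        # observed switches undercount crossovers slightly (between-marker gaps)
        assert 1.5 * 0.8 < mean <= 1.5 + 3 * np.std(switches) / np.sqrt(1000)


class TestArtifacts:
    def test_zero_rates_identity(self, clean_pop):
        geno, _, _ = clean_pop
        out, report = dm.inject_artifacts(geno, 0.0, 0.0, seed=1)
        assert np.array_equal(out.calls, geno.calls)
        assert report["n_set_missing"] == 0

    def test_missing_rate_binomial(self):
        geno, _, _ = dm.simulate_population(n_rils=305, n_chrom=2, snps_per_chrom=500, seed=1)
        out, _ = dm.inject_artifacts(geno, missing_rate=0.05, seed=2)
        frac = (out.calls == -1).mean()
        se = np.sqrt(0.05 * 0.95 / out.calls.size)
        assert abs(frac - 0.05) < 3 * se

    def test_full_het_error_limit(self):
        calls = np.array([[0, 2], [2, 0]], dtype=np.int8)
        geno = dm.GenotypeMatrix(calls=calls, snp_id=["a", "b"], chrom=[1, 1], pos=[1, 2])
        out, _ = dm.inject_artifacts(geno, het_error_rate=0.999999, seed=0)
        assert (out.calls == 1).all()

    def test_invalid_rates(self, clean_pop):
        geno, _, _ = clean_pop
        with pytest.raises(ConfigurationError):
            dm.inject_artifacts(geno, missing_rate=1.0)


class TestPhenotypes:
    def test_noise_free_limit_gives_constant_index(self, clean_pop):
        geno, _, _ = clean_pop
        arch = default_architecture(geno.n_snps, seed=0)
        for spec in arch.traits.values():
            spec.cv = 0.0
            spec.qtl = []
        pheno, _ = dm.simulate_phenotypes(geno, arch, seed=1)
        ti = dm.tolerance_table(pheno)
        for trait, col in [("maturity", "TI_maturity"), ("grain_yield", "TI_yield")]:
            expected = 100.0 * arch.traits[trait].regime_ratio
            assert np.allclose(ti[col], expected)

    def test_yield_index_right_skewed(self):
        geno, pheno, _ = dm.simulate_population(n_rils=305, n_chrom=3, snps_per_chrom=30, seed=21)
        ti = dm.tolerance_table(pheno)
        assert dm.summarize(ti["TI_yield"])["skewness"] > 0

    def test_habit_change_loading_drives_positive_logistic_slope(self):
        """Liability-threshold oracle: positive loading -> positive slope at n=5000."""
        geno, _, _ = dm.simulate_population(n_rils=5000, n_chrom=1, snps_per_chrom=20, seed=31)
        arch = default_architecture(geno.n_snps, seed=31)
        arch.habit_change_loading = 0.5
        pheno, _ = dm.simulate_phenotypes(geno, arch, seed=32)
        ti = dm.tolerance_table(pheno)
        fit = dm.univariate_logistic(ti["habit_change"], ti["TI_yield"])
        assert fit.converged and fit.slope > 0 and fit.p_value < 0.01

    def test_qtl_out_of_range_rejected(self, clean_pop):
        geno, _, _ = clean_pop
        arch = default_architecture(geno.n_snps, seed=0)
        arch.traits["maturity"].qtl = [(geno.n_snps + 5, 1.0, 1.0)]
        with pytest.raises(ConfigurationError):
            dm.simulate_phenotypes(geno, arch, seed=0)

    def test_truth_roundtrip_through_writers(self, tmp_path, clean_pop):
        from droughtmagic import io

        geno, pheno, truth = clean_pop
        path = tmp_path / "truth.tsv"
        io.write_truth(truth, geno, path)
        back = io.read_truth(path)
        n_expected = sum(len(v) for v in truth.qtl.values())
        assert len(back) == n_expected
        for (trait, regime), qtls in truth.qtl.items():
            sub = back[(back.trait == trait) & (back.regime == regime)]
            assert len(sub) == len(qtls)
            got = dict(zip(sub.snp_id, sub.effect))
            for idx, eff in qtls:
                assert got[geno.snp_id[idx]] == pytest.approx(eff, rel=1e-12)
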