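import numpy as np
import pytest
import statsmodels.api as sm

import droughtmagic as dm
from droughtmagic.gwas import (
    BlinkConfig,
    encode_genotypes,
    fem_scan,
    prune_candidates,
    select_qtn_set,
)
from _helpers import plant_qtl


class TestEncode:
    def test_mean_imputation(self):
        M, testable = encode_genotypes(np.array([[0], [2], [-1]], dtype=np.int8))
        assert M[:, 0].tolist() == [0.0, 2.0, 1.0]
        assert testable[0]

    def test_no_missing_identity(self):
        calls = np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8)
        M, _ = encode_genotypes(calls)
        assert np.array_equal(M, calls.astype(float))

    def test_monomorphic_flagged(self):
        M, testable = encode_genotypes(np.array([[1, 0], [1, 2]], dtype=np.int8))
        assert not testable[0] and testable[1]


class TestFemScan:
    def test_matches_ols_oracle_with_empty_qtns(self):
        """Simple-regression t-test oracle, agreement to >=10 digits."""
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, (120, 40)).astype(float)
        y = rng.normal(size=120)
        p, d = fem_scan(M, y, [])
        for j in range(40):
            res = sm.OLS(y, sm.add_constant(M[:, j])).fit()
            assert p[j] == pytest.approx(res.pvalues[1], rel=1e-10)
            assert d[j] == pytest.approx(res.params[1], rel=1e-10)

    def test_perfect_fit_underflows_gracefully(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, (60, 5)).astype(float)
        y = M[:, 2].copy()
        p, d = fem_scan(M, y, [])
        assert d[2] == pytest.approx(1.0)
        assert 0 < p[2] <= 1e-100

    def test_pseudo_qtn_excluded_from_own_test(self):
        rng = np.random.default_rng(2)
        M = rng.integers(0, 3, (100, 10)).astype(float)
        y = M[:, 3] + rng.normal(0, 0.5, 100)
        p_with, _ = fem_scan(M, y, [3])
        p_plain, _ = fem_scan(M, y, [])
        # no collinearity failure; the QTN's own test falls back to marginal
        assert np.isfinite(p_with[3])
        assert p_with[3] == pytest.approx(p_plain[3], rel=1e-10)

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(3)
        M = rng.integers(0, 3, (80, 30)).astype(float)
        p, _ = fem_scan(M, rng.normal(size=80), [0, 5])
        valid = p[~np.isnan(p)]
        assert ((valid > 0) & (valid <= 1)).all()


class TestPruneCandidates:
    def test_duplicate_marker_pruned(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 50).astype(float)
        M = np.column_stack([col, col, rng.integers(0, 3, 50)])
        p = np.array([1e-8, 2e-8, 3e-8])
        cfg = BlinkConfig(candidate_p_cap=1.0)
        assert prune_candidates(p, M, cfg) == [0, 2]

    def test_independent_markers_all_kept(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(200, 4))
        p = np.array([1e-9, 2e-9, 3e-9, 4e-9])
        cfg = BlinkConfig(candidate_p_cap=1.0)
        assert prune_candidates(p, M, cfg) == [0, 1, 2, 3]

    def test_hand_traced_greedy_rule(self):
        """r2 {(1,2): high, rest low}, p-order 1<2<3<4 -> keep {1,3,4}."""
        rng = np.random.default_rng(6)
        n = 400
        m1 = rng.integers(0, 3, n).astype(float)
        noise = rng.integers(0, 3, n).astype(float)
        m2 = np.where(rng.random(n) < 0.9, m1, noise)  # r2(1,2) ~ 0.8
        m3 = rng.integers(0, 3, n).astype(float)
        m4 = rng.integers(0, 3, n).astype(float)
        M = np.column_stack([m1, m2, m3, m4])
        r2_12 = dm.pairwise_r2(m1, m2)
        assert r2_12 >= 0.7
        p = np.array([1e-9, 2e-9, 3e-9, 4e-9])
        cfg = BlinkConfig(candidate_p_cap=1.0, ld_prune_r2=0.7)
        assert prune_candidates(p, M, cfg) == [0, 2, 3]


class TestSelectQtnSet:
    def test_recovers_strong_planted_effect(self):
        rng = np.random.default_rng(7)
        M = rng.integers(0, 3, (150, 20)).astype(float)
        y = 3.0 * M[:, 11] + rng.normal(0, 0.5, 150)
        chosen, effects = select_qtn_set([11, 4, 2], M, y, BlinkConfig())
        assert 11 in chosen
        assert effects[chosen.index(11)] == pytest.approx(3.0, abs=0.3)

    def test_pure_noise_selects_empty(self):
        """On noise the gated candidate list plus BIC keeps the set empty."""
        cfg = BlinkConfig()
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            M = rng.integers(0, 3, (100, 10)).astype(float)
            y = rng.normal(size=100)
            p, _ = fem_scan(M, y, [])
            candidates = prune_candidates(p, M, cfg)
            chosen, _ = select_qtn_set(candidates, M, y, cfg)
            empty += len(chosen) == 0
        assert empty >= 95

    def test_empty_candidates_empty_set(self):
        chosen, effects = select_qtn_set([], np.zeros((10, 2)), np.zeros(10), BlinkConfig())
        assert chosen == [] and len(effects) == 0


class TestBlink:
    def test_planted_qtl_detected_within_ld_block(self, qtl_geno):
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            j = int(rng.integers(qtl_geno.n_snps))
            while qtl_geno.column(j).std() == 0:
                j = int(rng.integers(qtl_geno.n_snps))
            y = plant_qtl(qtl_geno, j, h2=0.20, seed=seed)
            res = dm.blink(qtl_geno, y)
            if res.fallback:
                continue
            hits = res.table.index[res.table["significant"]]
            r2 = [
                dm.pairwise_r2(qtl_geno.column(int(h)), qtl_geno.column(j))
                for h in hits
                if qtl_geno.column(int(h)).std() > 0
            ]
            detected += any(r >= 0.7 for r in r2)
        assert detected >= int(0.9 * n_seeds)

    def test_permuted_phenotype_loses_signal(self, qtl_geno):
        lost = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            j = int(rng.integers(qtl_geno.n_snps))
            while qtl_geno.column(j).std() == 0:
                j = int(rng.integers(qtl_geno.n_snps))
            y = plant_qtl(qtl_geno, j, h2=0.20, seed=seed)
            res = dm.blink(qtl_geno, rng.permutation(y))
            if res.fallback:
                lost += 1
                continue
            hits = res.table.index[res.table["significant"]]
            r2 = [
                dm.pairwise_r2(qtl_geno.column(int(h)), qtl_geno.column(j))
                for h in hits
                if qtl_geno.column(int(h)).std() > 0
            ]
            lost += not any(r >= 0.7 for r in r2)
        assert lost >= 3

    def test_final_qtn_set_is_ld_pruned(self, qtl_geno):
        rng = np.random.default_rng(9)
        idx = rng.choice(qtl_geno.n_snps, 3, replace=False)
        M, _ = encode_genotypes(qtl_geno)
        y = sum(
            2.0 * (M[:, j] - M[:, j].mean()) for j in idx
        ) + rng.normal(0, 1, qtl_geno.n_samples)
        res = dm.blink(qtl_geno, y)
        q = res.qtn_indices
        for a in range(len(q)):
            for b in range(a + 1, len(q)):
                assert dm.pairwise_r2(qtl_geno.column(q[a]), qtl_geno.column(q[b])) < 0.7

    def test_detection_monotone_in_effect_size(self, qtl_geno):
        """Larger planted effects are detected at least as often."""
        rates = []
        for h2 in (0.05, 0.15, 0.30):
            det = 0
            for seed in range(10):
                rng = np.random.default_rng(3000 + seed)
                j = int(rng.integers(qtl_geno.n_snps))
                while qtl_geno.column(j).std() == 0:
                    j = int(rng.integers(qtl_geno.n_snps))
                y = plant_qtl(qtl_geno, j, h2=h2, seed=seed)
                res = dm.blink(qtl_geno, y)
                if res.fallback:
                    continue
                hits = res.table.index[res.table["significant"]]
                det += any(
                    dm.pairwise_r2(qtl_geno.column(int(h)), qtl_geno.column(j)) >= 0.7
                    for h in hits
                    if qtl_geno.column(int(h)).std() > 0
                )
            rates.append(det)
        assert rates[0] <= rates[1] + 1 and rates[1] <= rates[2] + 1
        assert rates[2] >= 9

    def test_binary_trait_recoded(self, qtl_geno):
        rng = np.random.default_rng(10)
        y = rng.choice([1.0, 9.0], qtl_geno.n_samples)
        res = dm.blink(qtl_geno, y)  # must not crash on 1/9 coding
        assert res.table["p"].dropna().between(0, 1).all()


class TestCallSignificant:
    def _table(self, lods):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(lods))],
                "lod": lods,
                "p": [10.0**-l for l in lods],
            }
        )

    def test_strict_threshold(self):
        table, fallback = dm.call_significant(self._table([4.06, 3.88, 2.95]))
        assert table["significant"].tolist() == [True, True, False]
        assert not fallback

    def test_fallback_top_five(self):
        table, fallback = dm.call_significant(
            self._table([2.9, 2.8, 2.7, 2.6, 2.5, 2.4, 2.3])
        )
        assert fallback
        assert table["significant"].sum() == 5
        assert table.loc[table["lod"] >= 2.5, "significant"].all()

    def test_boundary_lod_not_significant(self):
        table, fallback = dm.call_significant(self._table([3.0, 3.5]))
        assert table["significant"].tolist() == [False, True]
        assert not fallback

    def test_empty_result(self):
        table, fallback = dm.call_significant(self._table([]))
        assert len(table) == 0 and not fallback


def test_estimator_interface(qtl_geno):
    est = dm.BlinkGWAS(lod_threshold=3.0)
    assert est.get_params()["ld_prune_r2"] == 0.7
    y = plant_qtl(qtl_geno, 17, h2=0.3, seed=0)
    est.fit(qtl_geno, y)
    assert est.result_.table.shape[0] == qtl_geno.n_snps
    assert np.array_equal(est.lod_, est.result_.table["lod"].to_numpy())
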