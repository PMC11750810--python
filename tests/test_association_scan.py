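"""Mixed-model scan: kinship oracle, REML recovery, OLS equivalence, stepwise selection."""

import numpy as np
import pytest

from threshfdr import (
    KinshipMatrix,
    ibs_kinship,
    multi_locus_scan,
    reml_null,
    simulate_genotypes,
    single_locus_scan,
)
from threshfdr.association_scan import _reml_neg_loglik


class TestKinship:
    def test_identical_rows_unit_similarity(self):
        G = simulate_genotypes(4, 50, seed=1)
        G.dosages[1] = G.dosages[0]
        K = ibs_kinship(G)
        assert K.values[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_opposite_homozygotes_zero(self):
        import pandas as pd

        from threshfdr import GenotypeMatrix

        d = np.vstack([np.zeros(20, dtype=int), np.full(20, 2, dtype=int), np.ones(20, dtype=int)])
        meta = pd.DataFrame({"chrom": ["1A"] * 20, "pos_bp": np.arange(1, 21), "ref": "A", "alt": "T"})
        K = ibs_kinship(GenotypeMatrix(d, meta, ["a", "b", "c"]))
        assert K.values[0, 1] == pytest.approx(0.0)
        assert K.values[0, 2] == pytest.approx(0.5)

    def test_matches_per_pair_loop_oracle(self):
        G = simulate_genotypes(12, 80, seed=2)
        K = ibs_kinship(G).values
        d = G.dosages
        for i in range(12):
            for j in range(12):
                expected = np.mean((2.0 - np.abs(d[i] - d[j])) / 2.0)
                assert K[i, j] == pytest.approx(expected, abs=1e-12)


def _family_kinship(n_families=25, fam_size=20, corr=0.9):
    """Block-diagonal family kinship: strong structure = informative REML."""
    from scipy.linalg import block_diag

    fam = np.full((fam_size, fam_size), corr) + (1 - corr) * np.eye(fam_size)
    return KinshipMatrix(block_diag(*[fam] * n_families))


class TestReml:
    def test_null_trait_gives_small_genetic_share(self):
        # REML precision hinges on relatedness structure, so the null check
        # uses a family-structured kinship rather than an unrelated panel
        K = _family_kinship()
        hits = 0
        for seed in range(20):
            y = np.random.default_rng(seed).standard_normal(K.n)
            sg, se, _ = reml_null(y, K)
            hits += sg / (sg + se) < 0.05
        assert hits >= 18

    def test_h2_recovery(self):
        K = _family_kinship()
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(K.n))
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 99)
            g = L @ rng.standard_normal(K.n)
            g = g / g.std()
            y = np.sqrt(0.5) * g + np.sqrt(0.5) * rng.standard_normal(K.n)
            sg, se, _ = reml_null(y, K)
            ests.append(sg / (sg + se))
        assert abs(np.mean(ests) - 0.5) < 0.15

    def test_matches_grid_search_objective(self):
        rng = np.random.default_rng(5)
        G = simulate_genotypes(80, 150, seed=6)
        K = ibs_kinship(G)
        y = rng.standard_normal(80)
        sg, se, aux = reml_null(y, K)
        s, U = np.linalg.eigh(K.values)
        s = np.clip(s, 1e-10, None)
        ystar, Xstar = U.T @ y, U.T @ np.ones((80, 1))
        grid = np.linspace(-10, 10, 4001)
        best = min(_reml_neg_loglik(g, s, ystar, Xstar) for g in grid)
        assert aux["loglik"] == pytest.approx(-best, abs=1e-4)

    def test_rank_deficient_X_rejected(self):
        G = simulate_genotypes(30, 40, seed=7)
        K = ibs_kinship(G)
        X = np.ones((30, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_null(np.random.default_rng(0).standard_normal(30), K, X)


class TestSingleLocusScan:
    def test_equals_ols_under_identity_kinship(self, identity_kinship):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        G = simulate_genotypes(100, 60, seed=9)
        y = rng.standard_normal(100)
        scan = single_locus_scan(y, G, identity_kinship(100), vc=(0.0, 1.0))
        Gc = G.centered()
        for j in range(0, 60, 7):
            if np.ptp(Gc[:, j]) == 0:
                continue
            ols = sm.OLS(y, sm.add_constant(Gc[:, j])).fit()
            assert scan.p_raw[j] == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_planted_snp_is_top_hit(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            G = simulate_genotypes(200, 300, seed=seed, rho=0.0)
            Mc = G.centered()
            j = 150
            g = Mc[:, j]
            if g.std() == 0:
                continue
            # planted effect explaining ~20% of variance
            y = g / g.std() * np.sqrt(0.2) + rng.standard_normal(200) * np.sqrt(0.8)
            scan = single_locus_scan(y, G, KinshipMatrix(np.eye(200)), vc=(0.0, 1.0))
            hits += int(np.argmin(scan.p_raw)) == j
        assert hits >= 19

    def test_affine_invariance_of_pvalues(self):
        rng = np.random.default_rng(10)
        G = simulate_genotypes(120, 80, seed=11)
        K = ibs_kinship(G)
        y = rng.standard_normal(120)
        a = single_locus_scan(y, G, K)
        b = single_locus_scan(3.7 * y - 12.0, G, K)
        assert np.allclose(a.p_raw, b.p_raw, atol=1e-10)

    def test_monomorphic_snp_flagged(self):
        import pandas as pd

        from threshfdr import GenotypeMatrix

        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(50, 3))
        d[:, 1] = 0
        meta = pd.DataFrame({"chrom": ["1A"] * 3, "pos_bp": [1, 2, 3], "ref": "A", "alt": "T"})
        G = GenotypeMatrix(d, meta, [f"s{i}" for i in range(50)])
        scan = single_locus_scan(rng.standard_normal(50), G, KinshipMatrix(np.eye(50)), vc=(0.0, 1.0))
        assert scan.p_raw[1] == 1.0
        assert scan.table["beta"].iloc[1] == 0.0
        assert scan.table["monomorphic"].iloc[1]


class TestMultiLocusScan:
    def test_zero_steps_reduces_to_single_locus(self):
        rng = np.random.default_rng(13)
        G = simulate_genotypes(100, 120, seed=14)
        K = ibs_kinship(G)
        y = rng.standard_normal(100)
        multi = multi_locus_scan(y, G, K, max_steps=0)
        single = single_locus_scan(y, G, K)
        assert np.allclose(multi.p_raw, single.p_raw)
        assert multi.cofactors == []

    def test_null_trait_selects_nothing(self):
        clean = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = simulate_genotypes(120, 200, seed=seed + 50)
            K = ibs_kinship(G)
            scan = multi_locus_scan(rng.standard_normal(120), G, K)
            clean += len(scan.cofactors) == 0
        assert clean >= 9

    def test_two_planted_snps_recovered(self):
        found = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = simulate_genotypes(300, 250, seed=seed + 77, rho=0.0)
            Mc = G.centered()
            j1, j2 = 40, 200
            y = Mc[:, j1] + Mc[:, j2] + rng.standard_normal(300) * 0.8
            scan = multi_locus_scan(y, G, ibs_kinship(G))
            found += j1 in scan.cofactors and j2 in scan.cofactors
        assert found >= 9

    def test_type_one_error_calibrated_under_null(self, identity_kinship):
        # per-SNP level of the mixed-model test with K=I across repeated nulls
        rates = {0.05: [], 0.01: []}
        for seed in range(10):
            rng = np.random.default_rng(seed + 1000)
            G = simulate_genotypes(150, 500, seed=seed + 200)
            y = rng.standard_normal(150)
            scan = single_locus_scan(y, G, identity_kinship(150), vc=(0.0, 1.0))
            for a in rates:
                rates[a].append(np.mean(scan.p_raw < a))
        for a, vals in rates.items():
            se = np.sqrt(a * (1 - a) / (500 * len(vals)))
            assert abs(np.mean(vals) - a) < 3 * se + 0.002
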