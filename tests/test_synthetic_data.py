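"""Generator contracts: MAF laws, LD structure, truth bookkeeping, NUE arithmetic."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from threshfdr import (
    GenotypeMatrix,
    compute_nue,
    simulate_genotypes,
    simulate_pvalues,
    simulate_trait,
)
from threshfdr.synthetic_data import validate_phenotypes


class TestSimulateGenotypes:
    def test_forced_maf_half(self):
        G = simulate_genotypes(400, 1, maf_law=("uniform", 0.5, 0.5), rho=0.0, seed=1)
        freq = G.dosages.mean() / 2.0
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / (2 * 400))

    def test_same_seed_bit_identical(self):
        a = simulate_genotypes(40, 120, seed=7)
        b = simulate_genotypes(40, 120, seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snp_meta.equals(b.snp_meta)

    def test_invalid_maf_bounds_rejected(self):
        with pytest.raises(ValueError, match="MAF bounds"):
            simulate_genotypes(10, 10, maf_law=("uniform", 0.0, 0.6))
        with pytest.raises(ValueError, match="MAF bounds"):
            simulate_genotypes(10, 10, maf_law=("uniform", 0.6, 0.7))

    def test_rho_zero_gives_no_adjacent_ld(self):
        r2s = []
        for seed in range(20):
            G = simulate_genotypes(200, 100, rho=0.0, seed=seed, n_chromosomes=1)
            d = G.dosages.astype(float)
            for j in range(0, 99, 2):
                r = np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
                if np.isfinite(r):
                    r2s.append(r * r)
        assert np.mean(r2s) < 0.05

    def test_positive_rho_gives_adjacent_ld(self):
        G = simulate_genotypes(300, 200, rho=0.9, seed=3, n_chromosomes=1)
        d = G.dosages.astype(float)
        r2s = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2 for j in range(0, 199, 2)]
        assert np.nanmean(r2s) > 0.2

    def test_maf_law_mean_conserved(self):
        # mean simulated MAF close to the law's mean (uniform(0.1, 0.5) -> 0.3)
        G = simulate_genotypes(300, 2000, maf_law=("uniform", 0.1, 0.5), seed=5)
        f = G.dosages.mean(axis=0) / 2.0
        maf = np.minimum(f, 1 - f)
        se = maf.std() / np.sqrt(len(maf))
        assert abs(maf.mean() - 0.3) < 3 * se + 0.01

    def test_positions_strictly_increasing_within_chrom(self, small_panel):
        for _, grp in small_panel.snp_meta.groupby("chrom"):
            assert (np.diff(grp["pos_bp"].to_numpy()) > 0).all()

    def test_dosage_validation(self):
        import pandas as pd

        with pytest.raises(ValueError, match="dosage values"):
            GenotypeMatrix(
                np.array([[0, 3], [1, 2]]),
                pd.DataFrame({"chrom": ["1A", "1A"], "pos_bp": [1, 2], "ref": "A", "alt": "T"}),
                ["a", "b"],
            )


class TestSimulateTrait:
    def test_nonnull_count_arithmetic(self):
        G = simulate_genotypes(60, 1000, seed=2)
        _, truth = simulate_trait(G, pi0=0.99, seed=3)
        assert len(truth.nonnull_indices) == 10

    def test_pure_null_trait_gives_uniform_scan_pvalues(self, identity_kinship):
        from threshfdr import single_locus_scan
        from threshfdr.pheno_qc import aggregate_phenotype

        G = simulate_genotypes(150, 400, seed=4)
        table, truth = simulate_trait(G, pi0=1.0, h2=0.0, outlier_rate=0.0, seed=5)
        assert len(truth.nonnull_indices) == 0
        agg = aggregate_phenotype(table, "NUE")
        y = agg[agg["n_level"] == "low"].set_index("sample_id").loc[G.sample_ids, "value"].to_numpy()
        scan = single_locus_scan(y, G, identity_kinship(150), vc=(0.0, 1.0))
        assert kstest(scan.p_raw, "uniform").pvalue > 0.01

    def test_heritability_recovered(self):
        shares = []
        for seed in range(15):
            G = simulate_genotypes(500, 300, seed=seed)
            table, truth = simulate_trait(G, pi0=0.95, h2=0.5, outlier_rate=0.0, seed=seed + 1000)
            from threshfdr.pheno_qc import aggregate_phenotype

            agg = aggregate_phenotype(table, "NUE")
            y = agg[agg["n_level"] == "low"].set_index("sample_id").loc[G.sample_ids, "value"].to_numpy()
            g = truth.genetic_values
            r = np.corrcoef(y, g)[0, 1]
            shares.append(r * r)
        assert abs(np.mean(shares) - 0.5) < 0.1

    def test_degenerate_h2_rejected(self):
        G = simulate_genotypes(30, 50, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            simulate_trait(G, pi0=1.0, h2=1.0, poly_frac=0.0)

    def test_table_passes_validation(self, trait_panel):
        _, table, _ = trait_panel
        validate_phenotypes(table)


class TestSimulatePvalues:
    def test_null_uniformity(self):
        p, truth = simulate_pvalues(10_000, 1.0, 0.0, seed=1)
        assert len(truth.nonnull_indices) == 0
        assert kstest(p, "uniform").pvalue > 0.01

    def test_mixture_tail_matches_closed_form(self):
        # P(p < t) = pi0 t + pi1 Phi((mu - z_t) sqrt(k)) for the one-sided transform
        t = 0.001
        z_t = norm.isf(t)
        expected = 0.9 * t + 0.1 * norm.cdf((3.0 - z_t) * 1.0)
        fracs = [np.mean(simulate_pvalues(10_000, 0.9, 3.0, seed=s)[0] < t) for s in range(20)]
        mc_se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 4 * mc_se + 1e-3

    def test_truth_partition_covers_all_snps(self):
        p, truth = simulate_pvalues(500, 0.9, 2.0, seed=2)
        nonnull = truth.nonnull_set
        null_count = sum(1 for i in range(500) if i not in nonnull)
        assert null_count + len(nonnull) == truth.m == len(p)

    def test_invalid_pi0_rejected(self):
        with pytest.raises(ValueError, match="pi0"):
            simulate_pvalues(100, 1.2, 1.0)


class TestComputeNue:
    @pytest.mark.parametrize(
        "gy,gnc,sy,snc,ns,expected",
        [
            (8000, 2, 5000, 0.5, 110, (160.0, 25.0, 185.0, 8000 / 110)),
            (0, 2, 0, 0.5, 110, (0.0, 0.0, 0.0, 0.0)),
            (2640, 2, 0, 0.5, 110, (52.8, 0.0, 52.8, 24.0)),
        ],
    )
    def test_worked_examples(self, gy, gnc, sy, snc, ns, expected):
        gny, sny, nt, nue = compute_nue(gy, gnc, sy, snc, ns)
        assert np.allclose((gny, sny, nt, nue), expected)

    def test_zero_supply_rejected(self):
        with pytest.raises(ValueError, match="Ns"):
            compute_nue(100, 2, 50, 0.5, 0)


class TestIO:
    def test_vcf_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "panel.vcf"
        small_panel.to_vcf(path)
        back = GenotypeMatrix.from_vcf(path)
        assert np.array_equal(small_panel.dosages, back.dosages)
        assert list(back.snp_meta["pos_bp"]) == list(small_panel.snp_meta["pos_bp"])

    def test_dosage_csv_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "panel.csv"
        small_panel.to_dosage_csv(path)
        back = GenotypeMatrix.from_dosage_csv(path)
        assert np.array_equal(small_panel.dosages, back.dosages)

    def test_truth_json_round_trip(self, tmp_path, trait_panel):
        from threshfdr import TruthSet

        _, _, truth = trait_panel
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthSet.from_json(path)
        assert np.array_equal(back.nonnull_indices, truth.nonnull_indices)
        assert back.pi0_true == truth.pi0_true
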