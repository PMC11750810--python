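"""Genomic QC: MAF counting and filtering, exact HWE, EM-based LD, pruning rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import chi2

from threshfdr import (
    GenotypeMatrix,
    compute_maf,
    filter_maf,
    haplotype_ld,
    hwe_test,
    ld_threshold,
    pairwise_ld,
    simulate_genotypes,
)


def _matrix(cols, chrom="1A"):
    cols = np.asarray(cols)
    m = cols.shape[1]
    meta = pd.DataFrame(
        {"chrom": [chrom] * m, "pos_bp": np.arange(1, m + 1) * 1000, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(cols, meta, [f"s{i}" for i in range(cols.shape[0])])


class TestMaf:
    def test_counting(self):
        G = _matrix(np.array([[0], [1], [2], [1], [0]]))
        assert compute_maf(G)[0] == pytest.approx(0.4)

    def test_all_het_gives_half(self):
        G = _matrix(np.ones((6, 1), dtype=int))
        assert compute_maf(G)[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        G = _matrix(np.zeros((5, 1), dtype=int))
        assert compute_maf(G)[0] == 0.0

    def test_filter_counts(self):
        cols = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 2], [0, 0, 1], [0, 0, 2], [0, 0, 1], [0, 0, 0],
             [0, 0, 1], [0, 0, 0], [0, 1, 1]]
        )
        G = _matrix(cols)  # MAFs: 0.0, 0.1, 0.45
        with pytest.warns(UserWarning):
            assert filter_maf(G, 0.05).m == 2
        with pytest.warns(UserWarning):
            assert filter_maf(G, 0.2).m == 1

    def test_filter_idempotent_and_monotone(self, small_panel):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once = filter_maf(small_panel, 0.05)
            twice = filter_maf(once, 0.05)
            stricter = filter_maf(small_panel, 0.1)
        assert once.m == twice.m
        assert stricter.m <= once.m


def _hwe_oracle(n_ref, n_het, n_alt):
    """Independent brute-force enumeration of the exact conditional HWE test."""
    n = n_ref + n_het + n_alt
    na = 2 * n_ref + n_het  # ref-allele count
    probs = {}
    for h in range(0, min(na, 2 * n - na) + 1):
        if (na - h) % 2:
            continue
        logp = (
            h * np.log(2) - gammaln((na - h) / 2 + 1) - gammaln(h + 1) - gammaln((2 * n - na - h) / 2 + 1)
        )
        probs[h] = logp
    mx = max(probs.values())
    total = sum(np.exp(v - mx) for v in probs.values())
    pmf = {h: np.exp(v - mx) / total for h, v in probs.items()}
    obs = pmf[n_het]
    return sum(v for v in pmf.values() if v <= obs * (1 + 1e-12))


class TestHwe:
    def test_all_heterozygotes_extreme(self):
        G = _matrix(np.ones((100, 1), dtype=int))
        assert hwe_test(G)[0] < 1e-6

    def test_exact_proportions_maximal_p(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25).reshape(-1, 1)
        p = hwe_test(_matrix(col))[0]
        assert p == pytest.approx(_hwe_oracle(25, 50, 25), abs=1e-12)
        assert p > 0.9

    def test_monomorphic_convention(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test(_matrix(np.zeros((10, 1), dtype=int)))[0] == 1.0

    @pytest.mark.parametrize("counts", [(30, 10, 10), (5, 40, 5), (12, 25, 13), (45, 9, 1)])
    def test_matches_enumeration_oracle(self, counts):
        col = np.array([0] * counts[0] + [1] * counts[1] + [2] * counts[2]).reshape(-1, 1)
        assert hwe_test(_matrix(col))[0] == pytest.approx(_hwe_oracle(*counts), abs=1e-10)


class TestPairwiseLd:
    def test_duplicated_snp_perfect_ld(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50)
        G = _matrix(np.column_stack([col, col]))
        rec = pairwise_ld(G)[0]
        assert rec.r2 == pytest.approx(1.0, abs=1e-9)
        assert abs(rec.d_prime) == pytest.approx(1.0, abs=1e-9)

    def test_independent_pair_low_r2(self):
        vals = []
        for seed in range(50):
            G = simulate_genotypes(500, 2, rho=0.0, seed=seed, n_chromosomes=1)
            recs = pairwise_ld(G)
            if recs:
                vals.append(recs[0].r2)
        assert np.mean(vals) < 0.01

    def test_em_equals_phased_counting_on_haploid_encoding(self):
        # phased haplotypes rendered as homozygous diploids leave the EM no
        # ambiguity, so it must reproduce direct haplotype counting exactly
        _, hap = simulate_genotypes(100, 6, seed=13, rho=0.6, n_chromosomes=1, return_haplotypes=True)
        G = _matrix(2 * hap)
        recs = pairwise_ld(G)
        for rec in recs:
            dp, r2 = haplotype_ld(hap[:, rec.snp_a], hap[:, rec.snp_b])
            assert rec.r2 == pytest.approx(r2, abs=1e-10)
            assert rec.d_prime == pytest.approx(dp, abs=1e-10)

    def test_em_tracks_phased_truth_on_diploids(self):
        G, hap = simulate_genotypes(800, 10, seed=14, rho=0.7, n_chromosomes=1, return_haplotypes=True)
        recs = pairwise_ld(G)
        for rec in recs:
            _, r2 = haplotype_ld(hap[:, rec.snp_a], hap[:, rec.snp_b])
            assert rec.r2 == pytest.approx(r2, abs=0.05)

    def test_r2_bounds_and_chi2p(self, small_panel):
        recs = pairwise_ld(small_panel)
        for rec in recs:
            assert 0.0 <= rec.r2 <= 1.0
            assert abs(rec.d_prime) <= 1.0
            assert 0.0 <= rec.chi2_p <= 1.0

    def test_cross_chromosome_pairs_excluded(self):
        G = simulate_genotypes(50, 30, seed=15, n_chromosomes=3)
        recs = pairwise_ld(G)
        chroms = G.snp_meta["chrom"].to_numpy()
        for rec in recs:
            assert chroms[rec.snp_a] == chroms[rec.snp_b] == rec.chrom


class TestLdThreshold:
    def test_chi2_quantile_oracle(self):
        thr = ld_threshold([], 4.75, 221)
        expected = chi2.ppf(1 - 10**-4.75, 1) / 221
        assert thr.r2_star == pytest.approx(expected, abs=1e-12)
        assert thr.r2_star == pytest.approx(0.0833174, abs=1e-6)

    def test_limit_small_logp(self):
        assert ld_threshold([], 1e-9, 221).r2_star < 1e-6

    def test_doubling_n_halves_threshold(self):
        a = ld_threshold([], 3.0, 200).r2_star
        b = ld_threshold([], 3.0, 400).r2_star
        assert a == pytest.approx(2 * b)

    def test_cap_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert ld_threshold([], 50.0, 2).r2_star == 1.0

    def test_empirical_quantile_reported(self, small_panel):
        recs = pairwise_ld(small_panel)
        thr = ld_threshold(recs, 2.0, small_panel.n)
        assert 0.0 <= thr.empirical_quantile <= 1.0
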