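"""Genotype quality control: MAF filtering, exact HWE tests and adjacent-SNP LD.

LD between neighbouring SNPs (consecutive in position order on the same
chromosome, within a distance window) is summarised by D' and r2 from
haplotype frequencies estimated with the usual two-locus EM on unphased
diploids.  Significance of an r2 value uses the n*r2 ~ chi2(1) asymptotic,
which also yields the pruning rule: the smallest r2 whose LD test reaches a
chosen -log10 p at the panel's sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .synthetic_data import MISSING, GenotypeMatrix

__all__ = [
    "LDRecord",
    "LDThreshold",
    "compute_maf",
    "filter_maf",
    "hwe_test",
    "pairwise_ld",
    "haplotype_ld",
    "ld_threshold",
    "ld_records_frame",
]


@dataclass
class LDRecord:
    snp_a: int
    snp_b: int
    chrom: str
    dist_bp: int
    d_prime: float
    r2: float
    chi2_p: float
    em_converged: bool = True

    def __post_init__(self):
        if abs(self.d_prime) > 1 + 1e-9:
            raise ValueError("|D'| must be <= 1")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 must be in [0, 1]")
        if self.dist_bp < 0:
            raise ValueError("dist_bp must be >= 0")


@dataclass
class LDThreshold:
    r2_star: float
    logp_cut: float
    n: int
    empirical_quantile: float | None = None


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor-allele frequency over non-missing calls (NaN if all missing)."""
    d = G.dosages.astype(float)
    miss = G.dosages == MISSING
    d[miss] = np.nan
    n_called = (~miss).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_alt = np.nansum(d, axis=0) / (2.0 * n_called)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    if (n_called == 0).any():
        warnings.warn(f"{int((n_called == 0).sum())} SNP(s) are all-missing; MAF undefined", stacklevel=2)
        maf[n_called == 0] = np.nan
    return maf


def filter_maf(G: GenotypeMatrix, cut: float) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly above ``cut`` (metadata preserved)."""
    if not (0.0 < cut <= 0.5):
        raise ValueError("cut must be in (0, 0.5]")
    maf = compute_maf(G)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep = np.where(maf > cut)[0]
    removed = G.m - len(keep)
    if removed:
        warnings.warn(f"MAF filter at {cut} removed {removed} of {G.m} SNPs", stacklevel=2)
    if len(keep) == 0:
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
        empty = GenotypeMatrix.__new__(GenotypeMatrix)
        empty.dosages = G.dosages[:, :0]
        empty.snp_meta = G.snp_meta.iloc[:0].reset_index(drop=True)
        empty.sample_ids = list(G.sample_ids)
        return empty
    return GenotypeMatrix(
        G.dosages[:, keep],
        G.snp_meta.iloc[keep].reset_index(drop=True),
        list(G.sample_ids),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional HWE p-value (probability-mass method).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # count of the rarer allele
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + (2 * n - n_rare - hets) // 2 >= 0]
    hets = hets[(2 * n - n_rare - hets) >= 0]
    logw = (
        hets * np.log(2.0)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - n_rare - hets) / 2 + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_test(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP exact Hardy-Weinberg p-values (monomorphic SNPs get p = 1)."""
    p = np.ones(G.m)
    n_mono = 0
    for j in range(G.m):
        col = G.dosages[:, j]
        col = col[col != MISSING]
        if len(col) < 5:
            raise ValueError(f"SNP {j} has fewer than 5 non-missing calls")
        counts = np.bincount(col, minlength=3)
        if counts[0] + counts[1] == 0 or counts[1] + counts[2] == 0:
            n_mono += 1
            continue
        p[j] = _hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2]))
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic SNP(s): HWE p set to 1", stacklevel=2)
    return p


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _ld_from_hap_freqs(p11: float, pA: float, pB: float):
    """D' and r2 from the alt-alt haplotype frequency and allele frequencies."""
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = D / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    return float(np.clip(d_prime, -1, 1)), float(min(r2, 1.0))


def _em_pair(ga: np.ndarray, gb: np.ndarray, tol: float = 1e-12, max_iter: int = 2000):
    """EM haplotype-frequency estimate for one unphased diploid SNP pair.

    Returns (p11, pA, pB, converged).  Alleles are coded alt=1; p11 is the
    frequency of the alt-alt haplotype.
    """
    counts = np.zeros((3, 3))
    for a, b in zip(ga, gb):
        counts[a, b] += 1
    n = counts.sum()
    pA = (counts[1].sum() + 2 * counts[2].sum()) / (2 * n)
    pB = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return pA * pB, pA, pB, True

    # definite haplotype counts from everything except double heterozygotes
    base = np.zeros(4)  # 00, 01, 10, 11 (A-allele, B-allele)
    for a in range(3):
        for b in range(3):
            if a == 1 and b == 1:
                continue
            c = counts[a, b]
            if c == 0:
                continue
            # decompose genotype into its two (unique) haplotype alleles
            aa = (0, 0) if a == 0 else (1, 1) if a == 2 else (0, 1)
            bb = (0, 0) if b == 0 else (1, 1) if b == 2 else (0, 1)
            if a == 1:  # het at A, hom at B: phase known
                base[0 * 2 + bb[0]] += c
                base[1 * 2 + bb[1]] += c
            elif b == 1:  # hom at A, het at B
                base[aa[0] * 2 + 0] += c
                base[aa[1] * 2 + 1] += c
            else:
                base[aa[0] * 2 + bb[0]] += c
                base[aa[1] * 2 + bb[1]] += c
    ndh = counts[1, 1]

    # composite-LD start (gets the sign of D right)
    cov = np.cov(ga, gb, ddof=0)[0, 1] / 2.0
    f = np.array(
        [
            (1 - pA) * (1 - pB) + cov,
            (1 - pA) * pB - cov,
            pA * (1 - pB) - cov,
            pA * pB + cov,
        ]
    )
    f = np.clip(f, 1e-10, None)
    f /= f.sum()
    converged = False
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        c_coupling = f[0] * f[3] / denom if denom > 0 else 0.5
        new = base.copy()
        new[0] += ndh * c_coupling
        new[3] += ndh * c_coupling
        new[1] += ndh * (1 - c_coupling)
        new[2] += ndh * (1 - c_coupling)
        new /= 2 * n
        if np.abs(new - f).max() < tol:
            f = new
            converged = True
            break
        f = new
    return float(f[3]), float(pA), float(pB), converged


def pairwise_ld(G: GenotypeMatrix, max_dist_bp: float = 200e6) -> list:
    """LD records for adjacent same-chromosome SNP pairs within a distance window.

    Haplotype frequencies come from the two-locus EM; if the EM fails to
    converge the record is flagged and falls back to the composite (dosage
    correlation) estimate.  The chi-square p-value uses n*r2 ~ chi2(1) with n
    the number of jointly called individuals.
    """
    records = []
    meta = G.snp_meta
    chrom_arr = meta["chrom"].to_numpy()
    pos_arr = meta["pos_bp"].to_numpy()
    for j in range(G.m - 1):
        a, b = j, j + 1
        if chrom_arr[a] != chrom_arr[b]:
            continue
        dist = int(pos_arr[b] - pos_arr[a])
        if dist > max_dist_bp:
            continue
        ga, gb = G.dosages[:, a], G.dosages[:, b]
        ok = (ga != MISSING) & (gb != MISSING)
        ga, gb = ga[ok].astype(int), gb[ok].astype(int)
        n_used = len(ga)
        if n_used < 2:
            continue
        p11, pA, pB, conv = _em_pair(ga, gb)
        if not conv:
            warnings.warn(f"EM did not converge for pair ({a},{b}); composite fallback", stacklevel=2)
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(ga, gb)[0, 1]
            r = 0.0 if not np.isfinite(r) else r
            d_prime = np.sign(r) * min(abs(r), 1.0)
            r2 = min(r * r, 1.0)
        else:
            d_prime, r2 = _ld_from_hap_freqs(p11, pA, pB)
        chi2_p = float(chi2.sf(n_used * r2, df=1))
        records.append(LDRecord(a, b, str(chrom_arr[a]), dist, d_prime, r2, chi2_p, conv))
    return records


def haplotype_ld(hap_a: np.ndarray, hap_b: np.ndarray):
    """D' and r2 by direct counting on phased 0/1 haplotype vectors."""
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    pA, pB = hap_a.mean(), hap_b.mean()
    p11 = np.mean(hap_a * hap_b)
    return _ld_from_hap_freqs(p11, pA, pB)


def ld_records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_a": r.snp_a,
                "snp_b": r.snp_b,
                "chrom": r.chrom,
                "dist_bp": r.dist_bp,
                "d_prime": r.d_prime,
                "r2": r.r2,
                "chi2_p": r.chi2_p,
                "em_converged": r.em_converged,
            }
            for r in records
        ]
    )


def ld_threshold(records, logp_cut: float, n: int) -> LDThreshold:
    """r2 pruning threshold implied by the chi-square LD test.

    r2* = chi2_quantile(1, 1 - 10^-logp_cut) / n, capped at 1: the smallest r2
    whose LD test reaches -log10 p >= logp_cut at sample size n.  When LD
    records are supplied, the empirical quantile of observed r2 at r2* is
    reported alongside.
    """
    if logp_cut <= 0:
        raise ValueError("logp_cut must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    r2_star = chi2.ppf(1.0 - 10.0 ** (-logp_cut), df=1) / n
    if r2_star > 1.0:
        warnings.warn("requested significance unattainable at this n; threshold capped at 1", stacklevel=2)
        r2_star = 1.0
    quant = None
    if records:
        r2s = np.array([r.r2 for r in records])
        quant = float(np.mean(r2s <= r2_star))
    return LDThreshold(float(r2_star), float(logp_cut), int(n), quant)
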