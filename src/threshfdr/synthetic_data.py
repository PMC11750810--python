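"""Synthetic genotype, phenotype and p-value generators with known ground truth.

The generators emulate a wheat association panel: a few hundred inbred-ish
genotypes typed at thousands of biallelic SNPs with a realistic minor-allele
frequency spectrum and block-wise linkage disequilibrium, a nitrogen-use
efficiency (NUE) trait measured at two nitrogen fertilisation levels over
several years, and — for fast calibration work — p-value vectors drawn
directly from a two-group (null / non-null) model.  Every simulation returns
the ground truth needed to score discovery procedures downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from ._rng import as_rng

MISSING = -1

# Agronomic constants used to back plot records out of a simulated NUE value.
# Nitrogen supply (kg N/ha) at the two fertilisation levels of the study design.
N_SUPPLY = {"low": 110.0, "high": 220.0}
# Typical grain / straw nitrogen concentrations (%) for winter wheat.
_GNC_PCT = 2.0
_SNC_PCT = 0.5
_STRAW_TO_GRAIN = 0.55

__all__ = [
    "GenotypeMatrix",
    "TruthSet",
    "MISSING",
    "N_SUPPLY",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_pvalues",
    "compute_nue",
    "validate_phenotypes",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix (n genotypes x m SNPs) plus per-SNP metadata.

    ``dosages`` holds values in {0, 1, 2} with ``MISSING`` (-1) as sentinel.
    ``snp_meta`` is a DataFrame with columns chrom, pos_bp, ref, alt; positions
    are strictly increasing within each chromosome.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 genotypes and m >= 1 SNPs, got {n} x {m}")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2} or missing (-1)")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        for col in ("chrom", "pos_bp", "ref", "alt"):
            if col not in self.snp_meta.columns:
                raise ValueError(f"snp_meta missing column {col!r}")
        pos = self.snp_meta["pos_bp"].to_numpy()
        if (pos < 0).any():
            raise ValueError("pos_bp must be non-negative")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            p = grp["pos_bp"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError("pos_bp must be strictly increasing within chromosome")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def recode_signed(self) -> np.ndarray:
        """Dosages recoded to (-1, 0, 1); missing entries become NaN."""
        z = self.dosages.astype(float) - 1.0
        z[self.dosages == MISSING] = np.nan
        return z

    def centered(self, impute: bool = True) -> np.ndarray:
        """Per-SNP mean-centered dosage matrix; missing entries mean-imputed."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        mu = np.nanmean(d, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        if impute:
            d = np.where(np.isnan(d), mu[None, :], d)
        return d - mu[None, :]

    # -- I/O ---------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a minimal unphased VCF 4.2 (GT fields only)."""
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=threshfdr\n")
            for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
                length = int(grp["pos_bp"].max()) + 1000
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(str(s) for s in self.sample_ids) + "\n")
            meta = self.snp_meta
            for j in range(self.m):
                row = meta.iloc[j]
                calls = "\t".join(gt_code[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos_bp'])}\tsnp{j}\t{row['ref']}\t"
                    f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        chroms, poss, refs, alts, rows = [], [], [], [], []
        for var in vcf:
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0] if var.ALT else ".")
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING  # cyvcf2 gts012 unknown code
            rows.append(g)
        meta = pd.DataFrame({"chrom": chroms, "pos_bp": poss, "ref": refs, "alt": alts})
        return cls(np.array(rows, dtype=np.int8).T, meta, samples)

    def to_dosage_csv(self, path) -> None:
        df = pd.DataFrame(
            self.dosages.T,
            columns=[str(s) for s in self.sample_ids],
        )
        df.insert(0, "chrom", self.snp_meta["chrom"].to_numpy())
        df.insert(1, "pos_bp", self.snp_meta["pos_bp"].to_numpy())
        df.insert(2, "ref", self.snp_meta["ref"].to_numpy())
        df.insert(3, "alt", self.snp_meta["alt"].to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_dosage_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path)
        meta = df[["chrom", "pos_bp", "ref", "alt"]].reset_index(drop=True)
        samples = [c for c in df.columns if c not in ("chrom", "pos_bp", "ref", "alt")]
        dos = df[samples].to_numpy(dtype=np.int8).T
        return cls(dos, meta, samples)


@dataclass
class TruthSet:
    """Ground truth of a simulation: which SNPs carry real effects."""

    nonnull_indices: np.ndarray
    effect_sizes: np.ndarray
    pi0_true: float
    m: int
    genetic_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.nonnull_indices = np.asarray(self.nonnull_indices, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        expected = int(round((1.0 - self.pi0_true) * self.m))
        if len(self.nonnull_indices) != expected:
            raise ValueError(
                f"|nonnull| = {len(self.nonnull_indices)} but round((1-pi0)*m) = {expected}"
            )
        if len(self.effect_sizes) != len(self.nonnull_indices):
            raise ValueError("effect_sizes must align with nonnull_indices")

    @property
    def nonnull_set(self) -> set:
        return set(int(i) for i in self.nonnull_indices)

    def to_json(self, path) -> None:
        payload = {
            "nonnull_indices": [int(i) for i in self.nonnull_indices],
            "effect_sizes": [float(b) for b in self.effect_sizes],
            "pi0_true": float(self.pi0_true),
            "m": int(self.m),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["nonnull_indices"], dtype=int),
            np.asarray(d["effect_sizes"], dtype=float),
            d["pi0_true"],
            d["m"],
        )


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


def _draw_mafs(m: int, maf_law, rng: np.random.Generator) -> np.ndarray:
    kind = maf_law[0]
    if kind == "uniform":
        lo, hi = float(maf_law[1]), float(maf_law[2])
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5, got ({lo}, {hi})")
        if lo == hi:
            return np.full(m, lo)
        return rng.uniform(lo, hi, size=m)
    if kind == "beta":
        a, b = float(maf_law[1]), float(maf_law[2])
        if a <= 0 or b <= 0:
            raise ValueError("beta MAF law needs positive shape parameters")
        return np.clip(0.5 * rng.beta(a, b, size=m), 1e-4, 0.5)
    raise ValueError(f"unknown maf_law kind {kind!r}")


def simulate_genotypes(
    n: int,
    m: int,
    maf_law=("uniform", 0.05, 0.5),
    block_len: int = 50,
    rho: float = 0.7,
    seed=None,
    n_chromosomes: int = 3,
    return_haplotypes: bool = False,
):
    """Simulate a diploid dosage matrix with block-wise LD.

    Haplotypes are generated from a latent Gaussian copula: within an LD block
    the latent variables follow an AR(1) process with lag correlation ``rho``,
    and the allele at SNP j is 1 when the latent uniform falls below that SNP's
    alt-allele frequency (drawn from ``maf_law``).  Haplotypes are paired into
    diploids, so adjacent SNPs inside a block show positive r2 governed by
    ``rho`` while blocks are independent.

    Parameters
    ----------
    maf_law : ("uniform", lo, hi) with 0 < lo <= hi <= 0.5, or ("beta", a, b)
        (the beta draw is scaled onto (0, 0.5]).
    return_haplotypes : also return the underlying (2n x m) 0/1 haplotype
        matrix — useful as a phased oracle for LD estimators.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    rng = as_rng(seed)
    mafs = _draw_mafs(m, maf_law, rng)

    # chromosome assignment: contiguous, near-equal SNP counts
    n_chromosomes = max(1, min(n_chromosomes, m))
    sizes = np.full(n_chromosomes, m // n_chromosomes)
    sizes[: m % n_chromosomes] += 1
    chrom_labels = [f"{i + 1}A" for i in range(n_chromosomes)]
    chroms = np.repeat(chrom_labels, sizes)
    pos = np.empty(m, dtype=np.int64)
    start = 0
    for size in sizes:
        gaps = rng.integers(2_000, 60_000, size=size)
        pos[start : start + size] = np.cumsum(gaps)
        start += size

    hap = np.empty((2 * n, m), dtype=np.int8)
    sq = np.sqrt(1.0 - rho * rho)
    start = 0
    for size in sizes:  # blocks never span a chromosome boundary
        for b0 in range(start, start + size, block_len):
            b1 = min(b0 + block_len, start + size)
            L = b1 - b0
            eps = rng.standard_normal((2 * n, L))
            z = np.empty_like(eps)
            z[:, 0] = eps[:, 0]
            for j in range(1, L):
                z[:, j] = rho * z[:, j - 1] + sq * eps[:, j]
            hap[:, b0:b1] = (ndtr(z) < mafs[b0:b1][None, :]).astype(np.int8)
        start += size

    dosages = hap[0::2] + hap[1::2]
    meta = pd.DataFrame(
        {
            "chrom": chroms,
            "pos_bp": pos,
            "ref": np.full(m, "A"),
            "alt": np.full(m, "T"),
        }
    )
    G = GenotypeMatrix(dosages.astype(np.int8), meta, [f"g{i:04d}" for i in range(n)])
    if return_haplotypes:
        return G, hap
    return G


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def simulate_trait(
    G: GenotypeMatrix,
    pi0: float = 0.99,
    effect_sd: float = 1.0,
    h2: float = 0.5,
    outlier_rate: float = 0.02,
    seed=None,
    years=(2018, 2019, 2020),
    n_reps: int = 2,
    poly_frac: float = 0.3,
    level_means=(24.181, 12.1),
    level_sds=(8.0, 5.0),
):
    """Simulate an NUE-like phenotype table for a genotype panel.

    The genotype-level trait is ``y = sum_j M_.j beta_j + polygenic + e`` with
    the genetic share of variance scaled to ``h2``.  A fraction ``poly_frac``
    of the genetic variance comes from a dense polygenic background so that
    kinship-based variance-component models have something to absorb.  Plot
    records are laid out as years x replicates at two nitrogen levels; a
    fraction ``outlier_rate`` of records receives 5-SD contaminating Gaussian
    noise (field outliers are a feature of the data, so the generator makes
    them).  Agronomic columns (GY, GNC, SY, SNC, Ns) are backed out of the
    NUE value so that ``compute_nue`` reproduces it.

    Returns (PhenotypeTable DataFrame, TruthSet).  The TruthSet carries the
    standardized genotype-level genetic values for variance-share checks.
    """
    if not (0.0 <= pi0 <= 1.0):
        raise ValueError("pi0 must be in [0, 1]")
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be > 0")
    rng = as_rng(seed)
    n, m = G.n, G.m
    n_nonnull = int(round((1.0 - pi0) * m))
    Mc = G.centered()

    idx = np.sort(rng.choice(m, size=n_nonnull, replace=False)) if n_nonnull else np.array([], dtype=int)
    beta = rng.normal(0.0, effect_sd, size=n_nonnull)
    g_major = Mc[:, idx] @ beta if n_nonnull else np.zeros(n)

    if poly_frac > 0:
        alpha = rng.normal(0.0, 1.0, size=m) / np.sqrt(m)
        u = Mc @ alpha
    else:
        u = np.zeros(n)

    v_major, v_poly = np.var(g_major), np.var(u)
    if h2 > 0 and v_major == 0 and (poly_frac == 0 or v_poly == 0):
        raise ValueError("degenerate: h2 > 0 requested with no genetic variance source")
    parts = []
    if v_major > 0:
        w = 1.0 - poly_frac if v_poly > 0 and poly_frac > 0 else 1.0
        parts.append(np.sqrt(w) * g_major / np.sqrt(v_major))
    if v_poly > 0 and poly_frac > 0:
        w = poly_frac if v_major > 0 else 1.0
        parts.append(np.sqrt(w) * u / np.sqrt(v_poly))
    g_std = np.sum(parts, axis=0) if parts else np.zeros(n)
    if np.var(g_std) > 0:
        g_std = (g_std - g_std.mean()) / g_std.std()

    e_std = rng.standard_normal(n)
    y_std = np.sqrt(h2) * g_std + np.sqrt(1.0 - h2) * e_std

    records = []
    for level, mean_l, sd_l in zip(("low", "high"), level_means, level_sds):
        t = mean_l + sd_l * y_std
        year_eff = rng.normal(0.0, 0.10 * sd_l, size=len(years))
        ns = N_SUPPLY[level]
        for yi, year in enumerate(years):
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0.0, 0.15 * sd_l, size=n)
                contam = rng.random(n) < outlier_rate
                noise = noise + contam * rng.normal(0.0, 5.0 * sd_l, size=n)
                nue = np.maximum(t + year_eff[yi] + noise, 0.0)
                gy = nue * ns
                records.append(
                    pd.DataFrame(
                        {
                            "sample_id": G.sample_ids,
                            "n_level": level,
                            "year": year,
                            "rep": rep,
                            "GY": gy,
                            "GNC": _GNC_PCT,
                            "SY": _STRAW_TO_GRAIN * gy,
                            "SNC": _SNC_PCT,
                            "Ns": ns,
                            "NUE": nue,
                        }
                    )
                )
    table = pd.concat(records, ignore_index=True)
    truth = TruthSet(idx, beta, pi0, m, genetic_values=g_std)
    return table, truth


def validate_phenotypes(table: pd.DataFrame) -> None:
    """Raise if a phenotype table violates its value-range invariants."""
    required = {"sample_id", "n_level", "year", "rep", "GY", "GNC", "SY", "SNC", "Ns", "NUE"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (table["GY"] < 0).any() or (table["SY"] < 0).any():
        raise ValueError("GY and SY must be non-negative")
    for col in ("GNC", "SNC"):
        if ((table[col] < 0) | (table[col] > 100)).any():
            raise ValueError(f"{col} must be a percentage in [0, 100]")
    if (table.loc[table["NUE"].notna(), "Ns"] <= 0).any():
        raise ValueError("Ns must be > 0 wherever NUE is recorded")


# ---------------------------------------------------------------------------
# direct p-value simulation
# ---------------------------------------------------------------------------


def simulate_pvalues(m: int, pi0: float, mu: float, k_scale: float = 1.0, seed=None):
    """Two-group z/p simulator bypassing the genotype layer.

    Null z ~ N(0,1); non-null z ~ N(mu, 1/k_scale).  p is the one-sided
    upper-tail probability under N(0,1).  Returns (p, TruthSet).
    """
    if not (0.0 <= pi0 <= 1.0):
        raise ValueError("pi0 must be in [0, 1]")
    if k_scale <= 0:
        raise ValueError("k_scale must be > 0")
    rng = as_rng(seed)
    n_nonnull = int(round((1.0 - pi0) * m))
    idx = np.sort(rng.choice(m, size=n_nonnull, replace=False)) if n_nonnull else np.array([], dtype=int)
    z = rng.standard_normal(m)
    if n_nonnull:
        z[idx] = rng.normal(mu, 1.0 / np.sqrt(k_scale), size=n_nonnull)
    p = norm.sf(z)
    truth = TruthSet(idx, np.full(n_nonnull, float(mu)), pi0, m)
    return p, truth


# ---------------------------------------------------------------------------
# NUE arithmetic
# ---------------------------------------------------------------------------


def compute_nue(GY, GNC, SY, SNC, Ns):
    """Nitrogen bookkeeping of the NUE definition.

    GNY = GY*GNC/100 (grain N yield), SNY = SY*SNC/100 (straw N yield),
    Nt = GNY + SNY (total plant N at maturity) and NUE = Gw/Ns with grain
    weight Gw = GY, i.e. grain yield per unit nitrogen supplied.

    Accepts scalars or arrays; returns (GNY, SNY, Nt, NUE).
    """
    GY = np.asarray(GY, dtype=float)
    GNC = np.asarray(GNC, dtype=float)
    SY = np.asarray(SY, dtype=float)
    SNC = np.asarray(SNC, dtype=float)
    Ns = np.asarray(Ns, dtype=float)
    if (Ns <= 0).any():
        raise ValueError("Ns must be > 0 (nitrogen supply divides the yield)")
    if (GY < 0).any() or (SY < 0).any() or (GNC < 0).any() or (SNC < 0).any():
        raise ValueError("yields and concentrations must be non-negative")
    GNY = GY * GNC / 100.0
    SNY = SY * SNC / 100.0
    Nt = GNY + SNY
    NUE = GY / Ns
    if GNY.ndim == 0:
        return float(GNY), float(SNY), float(Nt), float(NUE)
    return GNY, SNY, Nt, NUE
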