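"""Mixed-model association scans producing the raw p-value vectors.

Single-locus scan: the mixed linear model y = X b + Z u + e with u ~ N(0,
K sigma_g^2) on an identity-by-state kinship K.  Variance components are
estimated once by REML on the null (no-marker) model and then held fixed
while every marker is tested by generalized least squares — the familiar
P3D/EMMAX approximation, which makes a desk-scale scan a single
eigendecomposition plus vectorized regressions.

Multi-locus scan: forward stepwise selection in the same machinery — scan,
absorb the most significant SNP as a fixed cofactor, rescan, until nothing
clears the stopping level (Bonferroni at 0.05/m by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .synthetic_data import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "ScanResult",
    "ibs_kinship",
    "reml_null",
    "single_locus_scan",
    "multi_locus_scan",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    basis: str = "IBS"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ScanResult:
    """Per-SNP effects and p-values from an association scan."""

    table: pd.DataFrame  # columns: chrom, pos_bp, beta, se, p_raw, neglog10p
    model: str
    vc: tuple  # (sigma_g2, sigma_e2)
    cofactors: list = field(default_factory=list)

    @property
    def p_raw(self) -> np.ndarray:
        return self.table["p_raw"].to_numpy()

    @property
    def neglog10p(self) -> np.ndarray:
        return self.table["neglog10p"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def ibs_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = mean over SNPs of (2 - |d_i - d_j|)/2.

    Missing dosages are skipped pairwise; a pair with no jointly called SNP is
    an error.  Identical rows give 1, opposite homozygotes give 0.
    """
    from .synthetic_data import MISSING

    d = G.dosages
    if (d == MISSING).any():
        dd = d.astype(float)
        dd[d == MISSING] = np.nan
        n = G.n
        K = np.empty((n, n))
        for i in range(n):
            diff = np.abs(dd - dd[i][None, :])
            shared = np.sum(~np.isnan(diff), axis=1)
            if (shared == 0).any():
                raise ValueError("a sample pair shares zero non-missing SNPs")
            K[i] = np.nanmean((2.0 - diff) / 2.0, axis=1)
        K = (K + K.T) / 2.0
    else:
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(d.astype(float), metric="cityblock"))
        K = 1.0 - D / (2.0 * G.m)
    return KinshipMatrix(K, basis="IBS")


def _bend_eigh(K: np.ndarray, tol: float = 1e-6):
    """Eigendecompose K; clip slightly negative eigenvalues, reject badly non-PSD."""
    s, U = np.linalg.eigh(K)
    floor = -tol * max(s.max(), 1.0)
    if s.min() < floor:
        raise ValueError(f"kinship not PSD beyond bending tolerance (min eig {s.min():.3g})")
    return np.clip(s, 1e-10, None), U


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_neg_loglik(log_delta: float, s: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray) -> float:
    """Profiled restricted negative log-likelihood over delta = sigma_e2/sigma_g2."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    XtWX = Xstar.T @ (w[:, None] * Xstar)
    XtWy = Xstar.T @ (w * ystar)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ystar - Xstar @ beta
    n, p = Xstar.shape
    rss = float(resid @ (w * resid))
    sigma_g2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_g2) + 1.0)
        - np.log(w).sum()
        + logdet_XtWX
    )
    return -ll


def reml_null(y: np.ndarray, K: KinshipMatrix, X: np.ndarray | None = None):
    """REML variance components (sigma_g2, sigma_e2) of the null mixed model.

    One eigendecomposition of K followed by 1-D optimization of the profiled
    restricted likelihood over the variance ratio (grid scan + local refine).
    Returns (sigma_g2, sigma_e2, aux) where aux carries the eigen pair and the
    maximized restricted log-likelihood for reuse by the scans.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.n != n:
        raise ValueError("y and K dimensions disagree")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")
    s, U = _bend_eigh(K.values)
    ystar = U.T @ y
    Xstar = U.T @ X

    grid = np.linspace(-10.0, 10.0, 41)
    vals = np.array([_reml_neg_loglik(g, s, ystar, Xstar) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, ystar, Xstar), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    XtWX = Xstar.T @ (w[:, None] * Xstar)
    beta = np.linalg.solve(XtWX, Xstar.T @ (w * ystar))
    resid = ystar - Xstar @ beta
    sigma_g2 = float(resid @ (w * resid)) / (n - X.shape[1])
    sigma_e2 = delta * sigma_g2
    aux = {
        "delta": delta,
        "eigvals": s,
        "eigvecs": U,
        "loglik": -float(min(res.fun, vals[i])),
    }
    return sigma_g2, sigma_e2, aux


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _gls_scan(ytil, Xtil, Gtil, df_resid):
    """Vectorized per-SNP GLS Wald tests on decorrelated data."""
    Q, _ = np.linalg.qr(Xtil)
    yr = ytil - Q @ (Q.T @ ytil)
    Gr = Gtil - Q @ (Q.T @ Gtil)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    yy = float(yr @ yr)
    mono = gg <= 1e-12 * max(np.max(gg), 1.0)
    gg_safe = np.where(mono, 1.0, gg)
    beta = gy / gg_safe
    rss = np.maximum(yy - beta * gy, 0.0)
    sigma2 = rss / df_resid
    se = np.sqrt(np.maximum(sigma2 / gg_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * t_dist.sf(np.abs(tstat), df_resid)
    beta[mono] = 0.0
    se[mono] = np.nan
    p[mono] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p, mono


def single_locus_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    X: np.ndarray | None = None,
    vc=None,
) -> ScanResult:
    """Single-locus mixed-model scan with variance components fixed from the null.

    Each SNP is tested by a two-sided Wald t-test in the GLS regression of y
    on [X, snp] after whitening with V = sigma_g2 K + sigma_e2 I.  Dosages are
    mean-centered (and missing values mean-imputed) per SNP.  Monomorphic SNPs
    get beta 0, p 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.n != n:
        raise ValueError("y and G dimensions disagree")
    if K is None:
        K = KinshipMatrix(np.eye(n))
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if vc is None:
        sigma_g2, sigma_e2, aux = reml_null(y, K, X)
    else:
        sigma_g2, sigma_e2 = vc
        s, U = _bend_eigh(K.values)
        aux = {"delta": sigma_e2 / max(sigma_g2, 1e-12), "eigvals": s, "eigvecs": U}
        if sigma_g2 <= 1e-12:
            aux["delta"] = np.inf

    s, U = aux["eigvals"], aux["eigvecs"]
    delta = aux["delta"]
    if np.isinf(delta):  # pure residual model: whitening is a scalar
        scale = np.ones(n)
        Ut = U.T
    else:
        scale = 1.0 / np.sqrt(s + delta)
        Ut = U.T
    ytil = scale * (Ut @ y)
    Xtil = scale[:, None] * (Ut @ X)
    Gc = G.centered()
    Gtil = scale[:, None] * (Ut @ Gc)

    df_resid = n - X.shape[1] - 1
    beta, se, p, mono = _gls_scan(ytil, Xtil, Gtil, df_resid)
    table = pd.DataFrame(
        {
            "chrom": G.snp_meta["chrom"].to_numpy(),
            "pos_bp": G.snp_meta["pos_bp"].to_numpy(),
            "beta": beta,
            "se": se,
            "p_raw": p,
            "neglog10p": -np.log10(p),
            "monomorphic": mono,
        }
    )
    return ScanResult(table, "single_locus", (sigma_g2, sigma_e2), [])


def multi_locus_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    max_steps: int = 10,
    alpha_stop: float | None = None,
    X: np.ndarray | None = None,
) -> ScanResult:
    """Forward stepwise multi-locus scan.

    Repeatedly runs a single-locus scan, adds the most significant SNP as a
    fixed cofactor, and rescans, stopping when the best p-value exceeds
    ``alpha_stop`` (Bonferroni 0.05/m by default) or after ``max_steps``
    inclusions.  Reported p-values come from the final cofactor model;
    cofactor SNPs themselves are flagged (p = 1 in the output since they sit
    in the fixed part).  Variance components are estimated once on the null
    model and reused (P3D).  Collinear candidates are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K is None:
        K = KinshipMatrix(np.eye(n))
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if alpha_stop is None:
        alpha_stop = 0.05 / G.m
    sigma_g2, sigma_e2, aux = reml_null(y, K, X)
    vc = (sigma_g2, sigma_e2)
    Gc = G.centered()

    cofactors: list = []
    Xcur = X
    result = single_locus_scan(y, G, K, Xcur, vc=vc)
    for _ in range(max_steps):
        p = result.p_raw.copy()
        p[result.table["monomorphic"].to_numpy()] = 1.0
        if cofactors:
            p[cofactors] = 1.0
        order = np.argsort(p, kind="stable")
        added = False
        for j in order:
            if p[j] > alpha_stop:
                break
            cand = Gc[:, j : j + 1]
            trial = np.hstack([Xcur, cand])
            # collinearity guard: candidate must add rank
            if np.linalg.matrix_rank(trial) <= np.linalg.matrix_rank(Xcur):
                warnings.warn(f"SNP {j} collinear with current cofactors; skipped", stacklevel=2)
                continue
            Xcur = trial
            cofactors.append(int(j))
            added = True
            break
        if not added:
            break
        result = single_locus_scan(y, G, K, Xcur, vc=vc)

    table = result.table.copy()
    if cofactors:
        table.loc[cofactors, ["beta", "p_raw"]] = [0.0, 1.0]
        table.loc[cofactors, "neglog10p"] = 0.0
        table["cofactor"] = False
        table.loc[cofactors, "cofactor"] = True
    else:
        table["cofactor"] = False
    return ScanResult(table, "multi_locus", vc, cofactors)
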