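"""Nonlinear FDR estimators: Storey q-values and Efron-style local FDR.

q-values give the tail-area (global) FDR attached to each test: q_i is the
smallest FDR at which test i would be called.  Local FDR works on the z-score
scale and is the per-test posterior null probability pi0 f0(z) / f(z) under a
two-group model, with the null component either theoretical N(0,1) or an
empirical null N(delta0, sigma0^2) fitted to the central mass of the z
histogram, and the marginal density f estimated by Lindsey's method (Poisson
regression of histogram counts on a spline basis).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import ndtri
from scipy.stats import norm

from .linear_adjustment import Pi0Estimate, _check_p

__all__ = ["EmpiricalNull", "LfdrFit", "qvalues", "pvalues_to_z", "empirical_null", "local_fdr"]


@dataclass
class EmpiricalNull:
    delta0: float
    sigma0: float
    pi0: float

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if not (0.0 < self.pi0 <= 1.0):
            raise ValueError("pi0 must be in (0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"delta0": self.delta0, "sigma0": self.sigma0, "pi0": self.pi0},
                fh,
                indent=1,
                sort_keys=True,
            )


@dataclass
class LfdrFit:
    z: np.ndarray
    f_hat: np.ndarray
    f0_params: tuple  # (delta0, sigma0)
    pi0: float
    lfdr: np.ndarray
    density_df: int
    bins: int

    def discoveries(self, cut: float = 0.2) -> np.ndarray:
        return np.where(self.lfdr <= cut)[0]


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def qvalues(p, pi0=1.0) -> np.ndarray:
    """Storey q-values: q_i = min over t >= p_i of pi0 * m * t / #{p <= t}.

    ``pi0`` may be a float or a Pi0Estimate.  Order-preserving in p and
    bounded below by pi0 * p.
    """
    p = _check_p(p)
    if isinstance(pi0, Pi0Estimate):
        pi0 = pi0.pi0_hat
    pi0 = float(pi0)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_s = pi0 * m * ps / ranks
    q_s = np.minimum(np.minimum.accumulate(q_s[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_s
    return q


# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------


def pvalues_to_z(p, direction: str = "one_sided") -> np.ndarray:
    """Map p-values to z-scores that are N(0,1) under the null.

    one_sided (default): z = Phi^-1(1 - p).  two_sided: z = Phi^-1(1 - p/2),
    which folds everything onto the positive axis.  p at 0 or 1 is clamped to
    machine-safe bounds with a warning.
    """
    p = np.asarray(p, dtype=float)
    if direction not in ("one_sided", "two_sided"):
        raise ValueError("direction must be 'one_sided' or 'two_sided'")
    eps = 1e-300
    hi = 1.0 - 1e-16
    clipped = (p <= 0) | (p >= 1)
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} p-value(s) at 0 or 1 clamped before z-transform", stacklevel=2)
    pc = np.clip(p, eps, hi)
    if direction == "two_sided":
        pc = pc / 2.0
    # -ndtri(p) == ndtri(1 - p) without cancellation for tiny p
    return -ndtri(pc)


# ---------------------------------------------------------------------------
# empirical null
# ---------------------------------------------------------------------------


def empirical_null(z, bins: int | None = None, halfwidth: float = 1.5, n_iter: int = 3) -> EmpiricalNull:
    """Central-matching fit of the empirical null N(delta0, sigma0^2) and pi0.

    A quadratic is fitted to the log-counts of the histogram's central region,
    which under the two-group model is dominated by nulls.  The central window
    is centred on the histogram mode with halfwidth ``halfwidth`` null SDs and
    is re-centred from the fitted (delta0, sigma0) for ``n_iter`` rounds, so
    the window tracks the null component even when non-nulls are plentiful.
    pi0 follows from the fitted central mass and is capped at 1.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if m < 200:
        raise ValueError("need m >= 200 z-scores for an empirical-null fit")
    if bins is None:
        bins = int(np.clip(np.sqrt(m), 40, 200))
    counts, edges = np.histogram(z, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    # initial window around the smoothed mode; z-scores put sigma near 1
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts, kernel, mode="same")
    delta = centers[int(np.argmax(smooth))]
    sigma = 1.0

    fit = None
    for _ in range(n_iter):
        lo, hi = delta - halfwidth * sigma, delta + halfwidth * sigma
        sel = (centers >= lo) & (centers <= hi) & (counts > 0)
        if sel.sum() < 10:
            raise ValueError("fewer than 10 populated central bins; cannot fit empirical null")
        x = centers[sel]
        yv = np.log(counts[sel].astype(float))
        w = counts[sel].astype(float)  # Poisson-motivated weights
        coef = np.polyfit(x, yv, deg=2, w=np.sqrt(w))
        c2, c1, c0 = coef
        if c2 >= -1e-12:
            raise ValueError("central log-counts not concave; empirical null undefined")
        sigma = float(np.sqrt(-1.0 / (2.0 * c2)))
        delta = float(c1 * sigma**2)
        a = c0 + delta**2 / (2.0 * sigma**2)
        pi0 = float(np.exp(a) * np.sqrt(2.0 * np.pi) * sigma / (m * width))
        fit = EmpiricalNull(delta, sigma, min(pi0, 1.0))
    return fit


# ---------------------------------------------------------------------------
# local FDR
# ---------------------------------------------------------------------------


def _spline_basis(x: np.ndarray, data: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design matrix with natural-spline-equivalent flexibility.

    ``df`` counts degrees of freedom the way natural-spline bases do, so the
    basis uses df - 1 interior knots placed at data quantiles.
    """
    lo, hi = data.min(), data.max()
    n_interior = max(df - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, 3).toarray()


def local_fdr(z, null, density_df: int = 12, bins: int = 120) -> LfdrFit:
    """Local FDR via Lindsey's method.

    ``null`` is an EmpiricalNull or a (delta0, sigma0, pi0) tuple (pass
    (0, 1, pi0) for the theoretical null).  Histogram counts of z are fitted
    by a Poisson regression on a cubic B-spline basis (``density_df`` basis
    functions), giving a smooth marginal density f; then
    lfdr_i = min(1, pi0 f0(z_i) / f(z_i)).  In the tails (beyond 2 null SDs
    from delta0) lfdr is cleaned up to be non-increasing in |z - delta0|.
    """
    import statsmodels.api as sm

    z = np.asarray(z, dtype=float)
    if isinstance(null, EmpiricalNull):
        delta0, sigma0, pi0 = null.delta0, null.sigma0, null.pi0
    else:
        delta0, sigma0, pi0 = null
    if sigma0 <= 0 or not (0.0 < pi0 <= 1.0):
        raise ValueError("invalid null parameters")
    if density_df >= bins / 4:
        raise ValueError("density_df too large for the bin count (overfit guard)")
    if density_df < 5:
        raise ValueError("density_df must be >= 5 (cubic basis needs 4)")
    if np.ptp(z) <= 0:
        raise ValueError("degenerate input: all z identical")

    counts, edges = np.histogram(z, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    X = _spline_basis(centers, z, density_df)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    log_fitted = X @ fit.params  # log expected counts per bin
    log_f_centers = log_fitted - np.log(len(z) * width)
    log_f = np.interp(z, centers, log_f_centers)
    f_hat = np.exp(log_f)

    f0 = norm.pdf(z, loc=delta0, scale=sigma0)
    lfdr = np.minimum(pi0 * f0 / f_hat, 1.0)

    # tail cleanup: monotone non-increasing in |z - delta0| on the signal side.
    # z-scores here come from one-sided (or folded two-sided) p-values, so
    # evidence accumulates in the right tail only; the left tail is null
    # territory and is left alone.
    order = np.argsort(z, kind="stable")
    zs = z[order]
    ls = lfdr[order]
    right = zs >= delta0 + 2.0 * sigma0
    if right.any():
        start = int(np.argmax(right))
        seed = ls[max(start - 1, 0)]
        ls[start:] = np.minimum.accumulate(np.concatenate([[seed], ls[start:]]))[1:]
    # left/null side: the slab sits to the right, so moving left the evidence
    # only weakens — lfdr climbs back toward 1 (guards the sparse left tail
    # against density-fit flare).
    left = zs <= delta0 - 2.0 * sigma0
    if left.any():
        stop = int(len(zs) - np.argmax(left[::-1]))
        seed = ls[stop] if stop < len(zs) else ls[stop - 1]
        ls[:stop] = np.maximum.accumulate(np.concatenate([[seed], ls[:stop][::-1]]))[1:][::-1]
    lfdr_clean = np.empty_like(ls)
    lfdr_clean[order] = ls
    return LfdrFit(z, f_hat, (delta0, sigma0), pi0, lfdr_clean, density_df, bins)
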