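"""Linear FWER/FDR adjustments and bootstrap estimation of the null proportion.

The six classical procedures are implemented in their canonical forms:
Bonferroni min(1, m p); Holm (step-down cummax of (m-i+1) p_(i)); Hochberg
(step-up cummin of (m-i+1) p_(i)); Benjamini-Hochberg (step-up cummin of
(m/i) p_(i)); Benjamini-Yekutieli (BH scaled by the harmonic sum); and Sidak
1 - (1-p)^m.  Adjusted values are capped at 1 and tied raw p-values share the
adjusted value of the latest tied rank.

pi0 — the proportion of true nulls — is estimated by the Storey lambda method
with the bootstrap tuning rule: pi0(lambda) = #{p > lambda} / (m (1-lambda)),
with lambda chosen to minimize the bootstrap mean-squared error against the
minimum pi0 over the lambda grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import as_rng

METHODS = ("bonferroni", "holm", "hochberg", "bh", "by", "sidak")

__all__ = ["AdjustmentResult", "Pi0Estimate", "METHODS", "adjust", "bootstrap_pi0", "threshold_line"]


@dataclass
class AdjustmentResult:
    method: str
    p_adj: np.ndarray
    alpha: float
    threshold_raw_p: float  # largest raw p rejected (nan if nothing rejected)
    discoveries: np.ndarray  # indices with p_adj <= alpha
    m: int

    @property
    def n_discoveries(self) -> int:
        return len(self.discoveries)


@dataclass
class Pi0Estimate:
    pi0_hat: float
    lam: float
    B: int
    se: float

    def __post_init__(self):
        if not (0.0 < self.pi0_hat <= 1.0):
            raise ValueError("pi0_hat must be in (0, 1]")


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    bad = np.where(~np.isfinite(p) | (p < 0) | (p > 1))[0]
    if len(bad):
        raise ValueError(f"p-values outside [0, 1] or non-finite at indices {bad[:10].tolist()}")
    if p.size < 1:
        raise ValueError("empty p-value vector")
    return p


def _share_tied_ranks(p_sorted: np.ndarray, adj_sorted: np.ndarray) -> np.ndarray:
    """Give tied raw p-values the adjusted value of the latest tied rank."""
    out = adj_sorted.copy()
    j = len(p_sorted) - 1
    while j > 0:
        i = j
        while i > 0 and p_sorted[i - 1] == p_sorted[j]:
            i -= 1
        if i < j:
            out[i : j + 1] = out[j]
        j = i - 1
    return out


def adjust(p, method: str, alpha: float = 0.05) -> AdjustmentResult:
    """Apply one of the six linear adjustments to a raw p-value vector."""
    p = _check_p(p)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)

    if method == "bonferroni":
        adj_s = np.minimum(m * ps, 1.0)
    elif method == "sidak":
        adj_s = 1.0 - (1.0 - ps) ** m
    elif method == "holm":
        adj_s = np.minimum(np.maximum.accumulate((m - i + 1) * ps), 1.0)
    elif method == "hochberg":
        adj_s = np.minimum(np.minimum.accumulate(((m - i + 1) * ps)[::-1])[::-1], 1.0)
    elif method == "bh":
        adj_s = np.minimum(np.minimum.accumulate((m / i * ps)[::-1])[::-1], 1.0)
    else:  # by
        c_m = np.sum(1.0 / np.arange(1, m + 1))
        adj_s = np.minimum(np.minimum.accumulate((c_m * m / i * ps)[::-1])[::-1], 1.0)

    adj_s = _share_tied_ranks(ps, adj_s)
    p_adj = np.empty(m)
    p_adj[order] = adj_s
    discoveries = np.where(p_adj <= alpha)[0]
    threshold = float(p[discoveries].max()) if len(discoveries) else float("nan")
    return AdjustmentResult(method, p_adj, alpha, threshold, discoveries, m)


def bootstrap_pi0(p, B: int = 2000, lambda_grid=None, seed=None) -> Pi0Estimate:
    """Storey pi0 with bootstrap selection of lambda.

    For each lambda on the grid, pi0(lambda) = #{p > lambda} / (m (1-lambda)).
    The with-replacement bootstrap of the p-vector is realised through its
    exact sufficient statistic: the interval counts of a resample follow a
    multinomial over the lambda-grid cells, so resampled pi0(lambda) values
    are drawn without materialising index arrays.  lambda minimising the
    bootstrap MSE against min_lambda pi0(lambda) is selected
    (Storey-Tibshirani rule).  A scalar lambda_grid fixes lambda directly.
    """
    p = _check_p(p)
    m = p.size
    if m < 50:
        raise ValueError("need m >= 50 p-values for a stable pi0 estimate")
    if B < 100:
        raise ValueError("B must be >= 100")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.951, 0.05)
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if ((lambda_grid < 0) | (lambda_grid >= 1)).any():
        raise ValueError("lambda values must lie in [0, 1)")
    rng = as_rng(seed)

    lam_sorted = np.sort(lambda_grid)
    n_above = np.array([np.sum(p > lam) for lam in lam_sorted], dtype=float)
    pi0_lam = n_above / (m * (1.0 - lam_sorted))

    # multinomial bootstrap over the grid-cell partition of [0, 1]
    edges = np.concatenate([[0.0], lam_sorted[lam_sorted > 0], [1.0]])
    cell_counts, _ = np.histogram(np.clip(p, 0.0, np.nextafter(1.0, 0.0)), bins=edges)
    probs = cell_counts / m
    draws = rng.multinomial(m, probs, size=B).astype(float)
    cum = draws.cumsum(axis=1)
    inner = lam_sorted[lam_sorted > 0]
    boot_above = np.empty((B, len(lam_sorted)))
    for k, lam in enumerate(lam_sorted):
        if lam == 0.0:
            # #{p* > 0} = m minus resampled mass at exactly 0 (none for continuous p)
            boot_above[:, k] = float(m)
        else:
            j = int(np.searchsorted(inner, lam))  # cells strictly below lam
            boot_above[:, k] = m - cum[:, j]
    boot_pi0 = boot_above / (m * (1.0 - lam_sorted)[None, :])

    if len(lam_sorted) == 1:
        lam_star_idx = 0
    else:
        target = pi0_lam.min()
        mse = np.mean((boot_pi0 - target) ** 2, axis=0)
        lam_star_idx = int(np.argmin(mse))
    lam_star = float(lam_sorted[lam_star_idx])
    pi0_hat = float(pi0_lam[lam_star_idx])
    se = float(boot_pi0[:, lam_star_idx].std(ddof=1))
    if pi0_hat <= 0.0:
        warnings.warn("all p-values below lambda; pi0 floored at 1/m", stacklevel=2)
        pi0_hat = 1.0 / m
    pi0_hat = min(pi0_hat, 1.0)
    return Pi0Estimate(pi0_hat, lam_star, B, se)


def threshold_line(m: int, alpha: float = 0.05, method: str = "bonferroni") -> float:
    """Fixed -log10 raw-p significance line implied by a single-step method.

    Only Bonferroni and Sidak define a data-independent line; the step-up/
    step-down procedures' cutoffs depend on the observed p-vector, so they
    are refused here with a pointer to ``adjust``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if method == "bonferroni":
        return float(-np.log10(alpha / m))
    if method == "sidak":
        return float(-np.log10(1.0 - (1.0 - alpha) ** (1.0 / m)))
    if method in METHODS:
        raise ValueError(
            f"{method!r} has a data-dependent cutoff; use adjust() and read threshold_raw_p"
        )
    raise ValueError(f"unknown method {method!r}")
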