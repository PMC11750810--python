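"""Phenotype quality control: Shapiro-Wilk normality and its bootstrap extension.

A single Shapiro-Wilk test on a field-trial trait vector is fragile when the
vector keeps its outliers (as the NUE data here does).  The bootstrap check
replicates the test over B with-replacement resamples — or, in the Bayesian
variant, over Dirichlet-weighted reconstructions of the sample — and reports
the mean replicate p-value with a two-tailed 95% percentile interval.  A mean
bootstrap p close to (or inside) that interval around the plain Shapiro p is
read as "the normality call is stable under resampling".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import shapiro

from ._rng import as_rng

__all__ = ["NormalityReport", "shapiro_pvalue", "bayesian_bootstrap_normality", "aggregate_phenotype"]


@dataclass
class NormalityReport:
    shapiro_p: float
    boot_mean_p: float
    boot_ci: tuple
    B: int
    mode: str

    def __post_init__(self):
        lo, hi = self.boot_ci
        for v in (self.shapiro_p, self.boot_mean_p, lo, hi):
            if not (0.0 <= v <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if lo > hi:
            raise ValueError("CI bounds inverted")
        # NB the mean of heavy-tailed replicate p-values can legitimately sit
        # outside the percentile interval (e.g. strongly non-normal input), so
        # the mean is not constrained to the CI.

    @property
    def normal(self) -> bool:
        """Decision rule: the bootstrap mean p does not contradict the point test."""
        return self.boot_mean_p > 0.05 or self.shapiro_p > 0.05

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "shapiro_p": self.shapiro_p,
                    "boot_mean_p": self.boot_mean_p,
                    "boot_ci": list(self.boot_ci),
                    "B": self.B,
                    "mode": self.mode,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def shapiro_pvalue(vec) -> float:
    """Shapiro-Wilk p-value; rejects constant or out-of-range input."""
    vec = np.asarray(vec, dtype=float)
    if not (3 <= len(vec) <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000 observations")
    if np.ptp(vec) == 0:
        raise ValueError("constant vector: Shapiro-Wilk statistic is undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(shapiro(vec).pvalue)


def _resample_indices(rng, B: int, n: int) -> np.ndarray:
    return rng.integers(0, n, size=(B, n))


def _weighted_quantile_sample(sorted_vec: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Reconstruct an n-point sample from the weighted empirical distribution."""
    n = len(sorted_vec)
    cw = np.cumsum(weights)
    cw /= cw[-1]
    probs = (np.arange(1, n + 1) - 0.5) / n
    pos = np.searchsorted(cw, probs, side="left")
    return sorted_vec[np.clip(pos, 0, n - 1)]


def bayesian_bootstrap_normality(
    vec, B: int = 2000, mode: str = "resample", seed=None, indices: np.ndarray | None = None
) -> NormalityReport:
    """Bootstrap stability of the Shapiro-Wilk normality call.

    mode="resample" (default) draws B with-replacement resamples of the vector
    and applies the test to each; mode="dirichlet" is the Bayesian bootstrap
    proper — Dirichlet(1,...,1) weights, test applied to a weighted-quantile
    reconstruction of the sample.  ``indices`` may supply a precomputed B x n
    resampling-index matrix (resample mode), which makes the replicate set
    independent of the order of ``vec``.
    """
    vec = np.asarray(vec, dtype=float)
    n = len(vec)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if B < 100:
        raise ValueError("B < 100 gives a meaningless bootstrap interval")
    if mode not in ("resample", "dirichlet"):
        raise ValueError("mode must be 'resample' or 'dirichlet'")
    rng = as_rng(seed)
    point_p = shapiro_pvalue(vec)

    ps = np.empty(B)
    if mode == "resample":
        if indices is None:
            indices = _resample_indices(rng, B, n)
        for b in range(B):
            s = vec[indices[b]]
            ps[b] = shapiro_pvalue(s) if np.ptp(s) > 0 else 0.0
    else:
        srt = np.sort(vec)
        W = rng.dirichlet(np.ones(n), size=B)
        for b in range(B):
            s = _weighted_quantile_sample(srt, W[b])
            ps[b] = shapiro_pvalue(s) if np.ptp(s) > 0 else 0.0

    lo, hi = np.percentile(ps, [2.5, 97.5])
    return NormalityReport(point_p, float(ps.mean()), (float(lo), float(hi)), B, mode)


def aggregate_phenotype(table: pd.DataFrame, trait: str = "NUE") -> pd.DataFrame:
    """Per-genotype, per-N-level mean of a trait over years and replicates.

    Missing values are skipped; genotypes absent at one N level are reported
    via a warning and simply not present for that level in the output.
    Returns a DataFrame (sample_id, n_level, value, n_records).
    """
    if trait not in table.columns:
        raise ValueError(f"trait column {trait!r} not in table")
    sub = table[["sample_id", "n_level", trait]].dropna(subset=[trait])
    grouped = sub.groupby(["sample_id", "n_level"], sort=True)[trait]
    out = grouped.agg(value="mean", n_records="size").reset_index()
    levels = table["n_level"].unique()
    counts = out.groupby("sample_id")["n_level"].nunique()
    partial = counts[counts < len(levels)]
    if len(partial):
        warnings.warn(
            f"{len(partial)} genotype(s) missing at some N level; excluded there",
            stacklevel=2,
        )
    n_skipped = len(table) - len(sub)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} record(s) with missing {trait}", stacklevel=2)
    return out
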