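"""Gibbs-sampling two-group threshold optimization.

The working-scale statistics (z-scores or -log10 p) are modelled as a
spike-and-slab mixture: with probability 1 - pi1 a value comes from the null
law f0 (N(0,1) on the z scale; the -log10 transform of a uniform p-value,
i.e. an Exponential(ln 10), on the -log10 p scale), and with probability pi1
from a Gaussian slab N(mu, 1/k).  mu acts as the sparsity/regularization
parameter (where the non-null mass sits) and k as the scaling/penalty
parameter (how concentrated it is).  Conjugate full conditionals give a
plain Gibbs sampler over (gamma, mu, k, pi1); the per-test posterior
non-null probabilities (ppi) then support threshold selection at a target
posterior false-discovery proportion, and score any externally supplied
discovery set via its posterior expected FDP (the "EBayes index").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._rng import as_rng

LN10 = np.log(10.0)

__all__ = ["GibbsPriors", "TwoGroupPosterior", "gibbs_fit", "select_threshold", "posterior_fdp", "geweke_score"]


@dataclass
class GibbsPriors:
    """Priors for the two-group sampler (uninformative to mildly informative).

    mu ~ N(m0, s0^2) truncated to mu > null mean (prevents label switching);
    k ~ Gamma(a_k, b_k); pi1 ~ Beta(a_pi, b_pi).  m0 defaults to the 90th
    percentile of the data when left as None.
    """

    m0: float | None = None
    s0: float = 2.0
    a_k: float = 1.0
    b_k: float = 1.0
    a_pi: float = 1.0
    b_pi: float = 19.0


@dataclass
class TwoGroupPosterior:
    values: np.ndarray
    scale: str  # "z" or "neglog10p"
    mu_draws: np.ndarray
    k_draws: np.ndarray
    pi1_draws: np.ndarray
    ppi: np.ndarray  # posterior non-null probability per test (post burn-in)
    n_samples: int
    burn_in: int
    seed: object = None
    null_mean: float = 0.0
    priors: GibbsPriors = field(default_factory=GibbsPriors)

    def __post_init__(self):
        if ((self.ppi < 0) | (self.ppi > 1)).any():
            raise ValueError("ppi must lie in [0, 1]")

    def _post(self, draws):
        return draws[self.burn_in :]

    @property
    def summaries(self) -> dict:
        out = {}
        for name, draws in (("mu", self.mu_draws), ("k", self.k_draws), ("pi1", self.pi1_draws)):
            d = self._post(draws)
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            out[name] = {"median": float(med), "ci95": [float(lo), float(hi)]}
        return out

    def to_json(self, path) -> None:
        payload = {
            "scale": self.scale,
            "n_samples": int(self.n_samples),
            "burn_in": int(self.burn_in),
            "summaries": self.summaries,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_samples),
                "mu": self.mu_draws,
                "k": self.k_draws,
                "pi1": self.pi1_draws,
            }
        )


def _null_logpdf(v: np.ndarray, scale: str) -> np.ndarray:
    if scale == "z":
        return -0.5 * np.log(2 * np.pi) - 0.5 * v * v
    # -log10 p of uniform p: density ln(10) * 10^(-v) on v >= 0
    out = np.where(v >= 0, np.log(LN10) - v * LN10, -np.inf)
    return out


def _truncnorm_draw(rng, mean: float, sd: float, lower: float) -> float:
    """One draw from N(mean, sd^2) truncated to (lower, inf), by inverse CDF."""
    a = ndtr((lower - mean) / sd)
    if a >= 1.0 - 1e-14:
        return lower + sd * 1e-8  # essentially all mass below the bound
    u = rng.uniform(a, 1.0)
    return mean + sd * ndtri(u)


def gibbs_fit(
    values,
    n_samples: int = 15000,
    burn_in: int = 5000,
    priors: GibbsPriors | None = None,
    scale: str = "z",
    seed=None,
) -> TwoGroupPosterior:
    """Fit the two-group spike-and-slab model by Gibbs sampling.

    Full conditionals: gamma_i ~ Bernoulli from the mixture odds; mu from its
    conjugate truncated-normal; k from its conjugate Gamma; pi1 from its
    conjugate Beta.  Deterministic trace under a fixed seed.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite working-scale values")
    m = v.size
    if m < 100:
        raise ValueError("need at least 100 tests")
    if not (0 <= burn_in < n_samples):
        raise ValueError("need n_samples > burn_in >= 0")
    if scale not in ("z", "neglog10p"):
        raise ValueError("scale must be 'z' or 'neglog10p'")
    rng = as_rng(seed)
    priors = priors or GibbsPriors()
    m0 = float(np.percentile(v, 90.0)) if priors.m0 is None else priors.m0
    s0, a_k, b_k, a_pi, b_pi = priors.s0, priors.a_k, priors.b_k, priors.a_pi, priors.b_pi
    null_mean = 0.0 if scale == "z" else 1.0 / LN10
    log_f0 = _null_logpdf(v, scale)

    mu = max(m0, null_mean + 1.0)
    k = 1.0
    pi1 = 0.05
    gamma = v >= np.percentile(v, 95.0)

    mu_draws = np.empty(n_samples)
    k_draws = np.empty(n_samples)
    pi1_draws = np.empty(n_samples)
    ppi_sum = np.zeros(m)

    for it in range(n_samples):
        # gamma | mu, k, pi1
        log_f1 = 0.5 * np.log(k) - 0.5 * np.log(2 * np.pi) - 0.5 * k * (v - mu) ** 2
        logit = np.log(pi1) - np.log1p(-pi1) + log_f1 - log_f0
        prob1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
        gamma = rng.random(m) < prob1
        n1 = int(gamma.sum())

        # mu | gamma, k  (conjugate normal, truncated above the null mean)
        prec = 1.0 / s0**2 + k * n1
        mean = (m0 / s0**2 + k * v[gamma].sum()) / prec
        mu = _truncnorm_draw(rng, mean, 1.0 / np.sqrt(prec), null_mean)

        # k | gamma, mu  (conjugate gamma)
        sse = float(((v[gamma] - mu) ** 2).sum())
        k = rng.gamma(a_k + n1 / 2.0, 1.0 / (b_k + sse / 2.0))

        # pi1 | gamma  (conjugate beta)
        pi1 = rng.beta(a_pi + n1, b_pi + m - n1)
        pi1 = min(max(pi1, 1e-12), 1 - 1e-12)

        mu_draws[it] = mu
        k_draws[it] = k
        pi1_draws[it] = pi1
        if it >= burn_in:
            ppi_sum += gamma

    ppi = ppi_sum / (n_samples - burn_in)
    return TwoGroupPosterior(
        v, scale, mu_draws, k_draws, pi1_draws, ppi, n_samples, burn_in, seed, null_mean, priors
    )


def select_threshold(post: TwoGroupPosterior, target_fdr: float = 0.05):
    """Largest ppi-ranked discovery set with posterior expected FDP <= target.

    Tests are sorted by decreasing posterior non-null probability; the
    discovery set is the longest prefix whose mean (1 - ppi) stays at or
    below ``target_fdr``.  Returns (working-scale cutoff, discovery indices);
    the cutoff is the value of the last included test (None if empty).
    """
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must be in (0, 1)")
    order = np.argsort(-post.ppi, kind="stable")
    cum_fdp = np.cumsum(1.0 - post.ppi[order]) / np.arange(1, len(order) + 1)
    ok = np.where(cum_fdp <= target_fdr)[0]
    if len(ok) == 0:
        return None, np.array([], dtype=int)
    size = int(ok.max()) + 1
    chosen = order[:size]
    cutoff = float(post.values[chosen].min())
    return cutoff, np.sort(chosen)


def posterior_fdp(post: TwoGroupPosterior, discovery_set) -> float:
    """Posterior expected false-discovery proportion of any discovery set.

    The mean of (1 - ppi) over the set — usable as a common index to compare
    discovery sets produced by unrelated procedures (BH, q-values, lfdr, ...).
    Empty sets score 0 by convention.
    """
    idx = np.asarray(list(discovery_set), dtype=int)
    if idx.size == 0:
        return 0.0
    if idx.min() < 0 or idx.max() >= len(post.ppi):
        raise ValueError("discovery index outside the scanned range")
    return float(np.mean(1.0 - post.ppi[idx]))


def geweke_score(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score between early and late segments of a chain."""
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    a = trace[: int(first * n)]
    b = trace[int((1 - last) * n) :]

    def _spectral_var(x):
        # batch-means variance of the mean (robust to autocorrelation)
        nb = max(int(np.sqrt(len(x))), 2)
        size = len(x) // nb
        means = x[: nb * size].reshape(nb, size).mean(axis=1)
        return means.var(ddof=1) / nb

    return float((a.mean() - b.mean()) / np.sqrt(_spectral_var(a) + _spectral_var(b)))
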