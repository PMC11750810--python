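# Methods

This note records the statistical models implemented in `threshfdr`, the
defaults that matter, what the simulators do and do not emulate, and the
design choices made where more than one reasonable construction existed.

## The problem

In a GWAS, m SNPs are tested simultaneously against a quantitative trait.
The package treats threshold selection as an estimation problem on the
resulting p-value vector under the two-group view: each test is null with
probability π₀ or non-null with probability π₁ = 1 − π₀, and every
thresholding procedure is judged by the false-discovery proportion (FDP) and
power of the set it declares significant.  All components are evaluated on
simulated data where the non-null set is known exactly.

## Synthetic data

**Genotypes.**  Haplotypes are generated from a latent Gaussian copula: inside
an LD block of `block_len` SNPs (default 50) the latent variables follow an
AR(1) process with lag correlation `rho` (default 0.7); the allele at SNP j
is the indicator that the latent uniform falls below that SNP's alt-allele
frequency, drawn from the MAF law (default uniform(0.05, 0.5)).  Haplotype
pairs form diploids.  This yields a tunable adjacent-pair r² without
coalescent machinery, at the price of no realistic recombination map, no
population structure and no mutation-age–frequency coupling: kinship in
these panels is essentially "unrelated individuals", which matters for what
REML can resolve (below).  Default scaled-down panel: n = 200 genotypes ×
m = 5,000 SNPs (the motivating wheat panel was 221 × 22,489), which keeps
the full pipeline in seconds.

**Trait.**  The genotype-level trait is y = Σ_{j∈nonnull} M_{·j} β_j + u + e
with β ~ N(0, effect_sd²) on round((1−π₀)·m) SNPs, a dense polygenic term u
(a `poly_frac` = 0.3 share of genetic variance, so kinship models have
something to absorb), and the genetic share scaled to h² (default 0.5).
Plot records are laid out as 3 years × 2 replicates at two nitrogen levels
(supply 110 and 220 kg N/ha); a 2% fraction of records receives 5-SD
contaminating Gaussian noise, because field NUE vectors keep their outliers.
Level means/SDs default to 24.181/8 (low N, matching the magnitude of the
motivating dataset) and 12.1/5 (high N — NUE roughly halves when supply
doubles).  Grain yield is backed out as GY = NUE·Ns with fixed grain/straw N
concentrations (2% and 0.5%), so the NUE bookkeeping
GNY = GY·GNC/100, SNY = SY·SNC/100, Nt = GNY + SNY, NUE = GY/Ns
round-trips exactly.  The generator does not emulate G×E beyond the two N
levels, spatial field trends, or trait-specific error laws; passing tests
therefore demonstrate procedure-level correctness and calibration, not
agronomic realism.

**Direct p-values.**  For calibration work the genotype layer is bypassed:
z ~ N(0,1) for nulls and N(μ, 1/k) for non-nulls, p one-sided upper-tail.
The closed-form mixture makes FDR/FWER claims checkable analytically.

## Phenotype QC

Shapiro–Wilk is applied to the per-genotype, per-N-level mean trait.  The
bootstrap extension replicates the test over B = 2000 resamples and reports
the replicate mean with a two-tailed 95% percentile interval.  Two modes:
`resample` (plain with-replacement resampling, the default) and `dirichlet`
(the Bayesian bootstrap proper: Dirichlet(1,…,1) weights, test applied to a
weighted-quantile reconstruction).  Both are offered because the two
descriptions of this procedure in the motivating analysis pointed at
different constructions; they agree on accept/reject in clearly normal and
clearly non-normal cases.  Note the replicate-mean can sit outside the
percentile interval when the replicate distribution is heavily skewed (badly
non-normal input); the report therefore does not constrain it to the CI.

## Genotype QC

MAF filtering retains SNPs with MAF strictly above the cut (0.001–0.05 are
the conventional grid).  HWE uses the exact conditional test (enumeration of
heterozygote counts given allele counts, probability-mass two-sided rule);
monomorphic SNPs get p = 1 and are flagged.  HWE is report-only by default —
the screen is exposed, the filtering level is the caller's decision
(`--hwe-alpha`).

Adjacent-SNP LD ("adjacent" = consecutive in position order on the same
chromosome, within a 200 Mb window) is computed from haplotype frequencies
estimated by the standard two-locus EM on unphased diploids, started from
the composite (dosage-covariance) estimate so the sign of D is right, with a
flagged composite-correlation fallback on non-convergence.  Significance
uses n·r² ~ χ²(1) with n the jointly-called sample count, and the pruning
rule inverts it: r²\* = χ²₁(1 − 10^(−logp_cut))/n, capped at 1.  At
n = 221 and −log10 p = 4.75 this gives r²\* ≈ 0.083; published r² thresholds
of 0.8–0.95 for such panels are not derivable from this (or any standard)
rule, so the rule is exposed as a parameterized function rather than claimed
to reproduce them.

## Association scans

Kinship is identity-by-state: K_ij = mean over SNPs of (2 − |d_i − d_j|)/2.
REML variance components of y = Xβ + Zu + e, Var(u) = K σg², come from a
single eigendecomposition of K and 1-D optimization of the profiled
restricted likelihood over δ = σe²/σg² (grid on log δ ∈ [−10, 10] plus
bounded refinement).  Each SNP is then tested by a two-sided GLS Wald t-test
with the null-model variance components held fixed — the P3D/EMMAX
approximation, a deliberate deviation from exact per-marker REML chosen for
desk-scale runtime.  With K = I and σg² = 0 the test reduces exactly to OLS.
Dosages are mean-centered and missing values mean-imputed per SNP;
monomorphic SNPs report β = 0, p = 1.

A caveat the tests encode: REML precision on σg² depends on relatedness
structure.  For unrelated copula panels the h² estimate is extremely noisy
(as with real GREML on small unrelated samples), so variance-component
recovery is validated on family-structured kinship matrices, where the
information is real.

The multi-locus scan is forward stepwise: scan, absorb the most significant
SNP as a fixed cofactor, rescan, until the best p exceeds `alpha_stop`
(default Bonferroni 0.05/m — the selection rule of the upstream multi-locus
tools is not published, so a conservative explicit default is used) or
`max_steps` = 10.  Collinear candidates are skipped; reported p-values come
from the final cofactor model, with cofactor SNPs flagged.

## Linear adjustments

The six procedures are implemented in their canonical forms (Bonferroni
min(1, m·p); Holm step-down cummax of (m−i+1)p₍ᵢ₎; Hochberg step-up cummin of
(m−i+1)p₍ᵢ₎; BH step-up cummin of (m/i)p₍ᵢ₎; BY = BH × Σ1/j; Šidák
1−(1−p)^m).  Printed variants of the BH/BY bounds circulating in the applied
literature (e.g. α(m+1)/2m) do not match the procedures their own citations
define; this package follows the cited originals.  Adjusted values are
capped at 1; tied raw p-values share the adjusted value of the latest tied
rank.  These orderings hold pointwise on every vector:
bonferroni ≥ holm ≥ hochberg ≥ bh and by ≥ bh.  A fixed −log10 p line exists
only for the single-step methods; the Bonferroni and Šidák lines differ by
the constant log₁₀(−ln(1−α)/α) ≈ 0.011 at α = 0.05 for every m (they never
coincide to three decimals, a small but persistent gap).

**π₀ estimation.**  π₀(λ) = #{p > λ}/(m(1−λ)) on the grid λ ∈ {0, 0.05, …,
0.95}, with λ chosen by the Storey–Tibshirani bootstrap rule (minimize
bootstrap MSE against the grid minimum), B = 2000.  The with-replacement
bootstrap is realised through its exact sufficient statistic: interval
counts of a resample are multinomial over the λ-grid cells, so resampled
π₀(λ) values are drawn directly without materialising index arrays —
distributionally identical to index resampling and orders of magnitude
faster.  A scalar λ (e.g. the conventional 0.05) bypasses selection.

## Nonlinear FDR

**q-values** follow the standard step-up minimization
q_i = min_{t ≥ p_i} π₀ m t / #{p ≤ t}; order-preserving, bounded below by
π₀p.

**z-transform.**  z = Φ⁻¹(1−p) (one-sided; a folded two-sided mode exists),
computed as −Φ⁻¹(p) to avoid cancellation at tiny p, with p clamped to
machine-safe bounds.

**Empirical null.**  Central matching: a quadratic is fitted to log-counts of
the central histogram region, giving N(δ₀, σ₀²) and π₀ from the fitted
central mass.  The central window is centred on the histogram mode with
halfwidth 1.5 σ₀ and re-centred from the fit over 3 rounds.  A mode-centred
window (rather than an interquartile one) is essential when the non-null
fraction is large: with π₀ = 0.5 and a well-separated alternative the 25–75%
quantile range of z spans the non-null component and the quadratic fit is no
longer a null fit, while the mode-centred window stays null-dominated.  The
initial window width assumes the input is on a z scale (σ near 1), which is
what `pvalues_to_z` produces.

**Local FDR.**  Lindsey's method: histogram z into `bins` = 120 cells, fit
counts by Poisson regression on a cubic B-spline basis, read off
f(z); then lfdr = min(1, π₀f₀(z)/f(z)).  `density_df` counts degrees of
freedom the way natural-spline bases do (df − 1 equally spaced interior
knots).  The default is df = 12: the log-density of a realistic two-group
mixture has a sharp shoulder between bulk and tail, and stiffer fits (df
around 7) leave a systematic lfdr bias of ~0.04 in exactly the transition
region where thresholds live; df = 12 resolves the shoulder while the
overfit guard (df < bins/4) still holds.  Tail cleanup enforces that lfdr is
non-increasing moving right of δ₀ + 2σ₀ (the signal side for one-sided z)
and non-decreasing moving left of δ₀ − 2σ₀ toward 1 (the null side — a
right-shifted slab's likelihood ratio dies in the left tail), which also
guards both sparse tails against density-fit flare.

## Gibbs threshold optimization

The two-group spike-and-slab model on the working scale v (z-scores, or
−log10 p where the null law is the transform of a uniform p-value, i.e.
Exponential(ln 10)): v_i | γ_i = 0 ~ f₀ and v_i | γ_i = 1 ~ N(μ, 1/k).  μ is
the sparsity/regularization parameter (where non-null mass sits), k the
scaling/penalty parameter (its concentration).  Priors, uninformative to
mildly informative: μ ~ N(m₀, s₀²) truncated to μ > null mean (prevents
label switching), m₀ defaulting to the 90th percentile of the data and
s₀ = 2; k ~ Gamma(1, 1); π₁ ~ Beta(1, 19).  All full conditionals are
conjugate (Bernoulli / truncated-normal / Gamma / Beta), giving a plain
Gibbs sweep; defaults 15,000 samples with 5,000 burn-in.  The source
material for this component never wrote down a likelihood; the spike-and-
slab above is this package's concrete instantiation of its sparsity+scaling
description.

Posterior non-null probabilities ppi (post-burn-in mean of γ) drive two
consumers: `select_threshold` takes the longest ppi-ranked prefix whose mean
(1 − ppi) stays at or below the target FDR, and `posterior_fdp` scores *any*
discovery set by its posterior expected FDP — a common index that lets
unrelated procedures (BH, q-values, lfdr) be compared on one scale without
access to the truth.

## Pipeline

`run_pipeline` chains simulate → genotype QC → trait → phenotype QC → scan →
adjustments → q/lfdr → Gibbs → comparison, writing every intermediate as
plain text (VCF, CSV, TSV, JSON).  Genotypes are MAF-filtered before the
trait is simulated so truth indices always refer to the scanned panel.  Low-
and high-N arms are two independent runs differing in the configured level.
All randomness flows from one master seed through named substreams
(SHA-256-derived SeedSequences), so any stage replays independently and the
comparison table is byte-identical across runs.

## Problem sizes used in checks

The test suite and the acceptance script use: m = 2,000 × 1,000–1,500
replicates for family-wise error; m = 10,000 × 20 seeds for FDR calibration
and π₀/empirical-null recovery (non-null mean μ = 4 for recovery studies, a
clearly separated alternative); m = 50,000 for the closed-form lfdr
comparison; m = 2,000 with 15,000 Gibbs samples × 10–20 seeds at the
operating point μ = 5.8, k = 0.25, π₁ = 0.05 on the −log10 p scale; and
n = 200 × m = 5,000 for scan-level checks.  These sizes were chosen so every
Monte-Carlo standard error is small relative to the tolerance being checked.

## Known limitations

- No population structure or cryptic relatedness in the simulator, hence no
  stress test of the kinship correction against stratification.
- The empirical-null fit assumes a unimodal central null; bimodal z
  histograms (e.g. strong batch mixtures) will be rejected, not mis-fit.
- The Gibbs model has a single Gaussian slab; multimodal alternatives are
  absorbed into (μ, k) averages.
- `threshold_line` exists only for single-step methods by construction; the
  step-up/step-down procedures have data-dependent cutoffs.
- The multi-locus scan fixes variance components from the null model (P3D);
  very strong cofactors can make that approximation visible.
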