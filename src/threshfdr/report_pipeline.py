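"""End-to-end orchestration and truth-based cross-method comparison.

``method_comparison`` scores every thresholding procedure — the six linear
adjustments, q-values, local FDR and the Gibbs posterior selector — on the
same p-value vector against a known truth set, reporting discoveries,
realized false-discovery proportion, power, the raw-p threshold each method
implies, and the common posterior-FDP (EBayes) index from the fitted
two-group model.  ``run_pipeline`` drives the full simulate / QC / scan /
adjust / estimate / optimize / report chain from a config mapping (or YAML
file), with all randomness flowing from one master seed through named
substreams so any stage is independently replayable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .association_scan import ScanResult, ibs_kinship, multi_locus_scan, single_locus_scan
from .fdr_nonlinear import EmpiricalNull, empirical_null, local_fdr, pvalues_to_z, qvalues
from .geno_qc import filter_maf, hwe_test, ld_records_frame, pairwise_ld
from .linear_adjustment import METHODS, adjust, bootstrap_pi0
from .pheno_qc import aggregate_phenotype, bayesian_bootstrap_normality
from .synthetic_data import TruthSet, simulate_genotypes, simulate_trait
from .threshold_optimizer import gibbs_fit, posterior_fdp, select_threshold

__all__ = ["MethodEvaluation", "evaluate_against_truth", "method_comparison", "run_pipeline", "default_config"]


@dataclass
class MethodEvaluation:
    method: str
    n_discoveries: int
    fdp: float
    power: float
    ebayes_index: float
    threshold_raw_p: float

    def __post_init__(self):
        for v in (self.fdp, self.power):
            if not (0.0 <= v <= 1.0):
                raise ValueError("fdp and power must lie in [0, 1]")


def evaluate_against_truth(discoveries, truth: TruthSet) -> dict:
    """Exact TP/FP bookkeeping of a discovery set against the simulation truth.

    FDP = FP / max(1, |discoveries|); power = TP / |nonnull| (0 when there
    are no non-nulls).
    """
    idx = np.asarray(list(discoveries), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= truth.m):
        raise ValueError("discovery index outside the SNP range covered by the truth set")
    nonnull = truth.nonnull_set
    tp = sum(1 for i in idx if int(i) in nonnull)
    fp = len(idx) - tp
    fdp = fp / max(1, len(idx))
    power = tp / len(nonnull) if nonnull else 0.0
    return {
        "n_discoveries": int(len(idx)),
        "tp": int(tp),
        "fp": int(fp),
        "tn": int(truth.m - len(nonnull) - fp),
        "fn": int(len(nonnull) - tp),
        "fdp": float(fdp),
        "power": float(power),
    }


def _threshold_raw_p(p: np.ndarray, idx: np.ndarray) -> float:
    return float(p[idx].max()) if len(idx) else float("nan")


def method_comparison(
    scan,
    truth: TruthSet,
    alpha: float = 0.05,
    lfdr_cut: float = 0.2,
    target_fdr: float = 0.05,
    gibbs_samples: int = 15000,
    gibbs_burn_in: int = 5000,
    pi0_lambda=None,
    density_df: int = 7,
    bins: int = 120,
    seed=None,
) -> pd.DataFrame:
    """Score all nine thresholding procedures on one scan against the truth.

    ``scan`` is a ScanResult or a raw p-value array.  Returns one row per
    method, serialized deterministically (fixed row and column order).
    Component failures (e.g. an empirical-null fit refusing a degenerate
    histogram) degrade to annotated partial rows rather than aborting.
    """
    p = scan.p_raw if isinstance(scan, ScanResult) else np.asarray(scan, dtype=float)
    m = p.size
    z = pvalues_to_z(p)
    post = gibbs_fit(z, n_samples=gibbs_samples, burn_in=gibbs_burn_in, scale="z", seed=seed)

    rows = []

    def add_row(name, idx, note=""):
        ev = evaluate_against_truth(idx, truth)
        rows.append(
            {
                "method": name,
                "n_discoveries": ev["n_discoveries"],
                "fdp": ev["fdp"],
                "power": ev["power"],
                "ebayes_index": posterior_fdp(post, idx),
                "threshold_raw_p": _threshold_raw_p(p, np.asarray(list(idx), dtype=int)),
                "note": note,
            }
        )

    for method in METHODS:
        res = adjust(p, method, alpha=alpha)
        add_row(method, res.discoveries)

    try:
        pi0 = bootstrap_pi0(p, lambda_grid=pi0_lambda, seed=seed)
        q = qvalues(p, pi0)
        add_row("qvalue", np.where(q <= alpha)[0], note=f"pi0={pi0.pi0_hat:.4f}")
    except Exception as exc:  # degrade to a partial table
        rows.append({"method": "qvalue", "n_discoveries": 0, "fdp": 0.0, "power": 0.0,
                     "ebayes_index": float("nan"), "threshold_raw_p": float("nan"),
                     "note": f"failed: {exc}"})

    try:
        try:
            null = empirical_null(z)
        except ValueError:
            null = EmpiricalNull(0.0, 1.0, 1.0)
        fit = local_fdr(z, null, density_df=density_df, bins=bins)
        add_row("lfdr", fit.discoveries(lfdr_cut), note=f"pi0={null.pi0:.4f}")
    except Exception as exc:
        rows.append({"method": "lfdr", "n_discoveries": 0, "fdp": 0.0, "power": 0.0,
                     "ebayes_index": float("nan"), "threshold_raw_p": float("nan"),
                     "note": f"failed: {exc}"})

    _, gibbs_idx = select_threshold(post, target_fdr)
    add_row("gibbs", gibbs_idx)

    return pd.DataFrame(rows, columns=["method", "n_discoveries", "fdp", "power",
                                       "ebayes_index", "threshold_raw_p", "note"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def default_config() -> dict:
    return {
        "out_dir": "threshfdr_run",
        "master_seed": 1,
        "simulate": {
            "n": 200,
            "m": 5000,
            "maf_law": ["uniform", 0.05, 0.5],
            "block_len": 50,
            "rho": 0.7,
            "pi0": 0.99,
            "effect_sd": 1.0,
            "h2": 0.5,
            "outlier_rate": 0.02,
            "n_level": "low",
        },
        "qc": {"maf_cut": 0.05, "hwe_alpha": None, "bootstrap_B": 2000},
        "scan": {"model": "single", "max_steps": 10},
        "adjust": {"alpha": 0.05},
        "fdr": {"lfdr_cut": 0.2, "density_df": 7, "bins": 120},
        "optimize": {"samples": 15000, "burn_in": 5000, "target_fdr": 0.05},
        "report": {},
    }


_REQUIRED_SECTIONS = ("out_dir", "master_seed", "simulate", "qc", "scan", "adjust", "fdr", "optimize", "report")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to a YAML file")
    merged = default_config()
    for key in config:
        if key not in _REQUIRED_SECTIONS:
            raise KeyError(f"unknown config section {key!r}")
        if isinstance(merged.get(key), dict):
            unknown = set(config[key]) - set(merged[key])
            if unknown:
                raise KeyError(f"unknown key(s) {sorted(unknown)} in section {key!r}")
            merged[key].update(config[key])
        else:
            merged[key] = config[key]
    return merged


def run_pipeline(config, force: bool = False) -> Path:
    """Run the full simulate -> QC -> scan -> adjust -> estimate -> optimize -> report chain.

    Writes genotypes (VCF + dosage CSV), phenotypes, truth, QC reports, the
    scan table, adjusted p-values, q/lfdr estimates, the posterior summary and
    trace, and the cross-method comparison table into ``out_dir``.  Refuses an
    existing output directory unless ``force``.
    """
    cfg = _load_config(config)
    out = Path(cfg["out_dir"])
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} exists; pass force=True (--force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["master_seed"])
    log = {"master_seed": master, "stages": {}}

    # 1. genotypes
    sim = cfg["simulate"]
    G = simulate_genotypes(
        sim["n"], sim["m"], maf_law=tuple(sim["maf_law"]), block_len=sim["block_len"],
        rho=sim["rho"], seed=substream(master, "genotypes"),
    )
    G.to_vcf(out / "genotypes.vcf")
    G.to_dosage_csv(out / "dosages.csv")

    # 2. genomic QC (filter first so truth indices refer to the scanned panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Gf = filter_maf(G, cfg["qc"]["maf_cut"])
        hwe_p = hwe_test(Gf)
        records = pairwise_ld(Gf)
    ld_records_frame(records).to_csv(out / "ld_records.tsv", sep="\t", index=False)
    pd.DataFrame({"hwe_p": hwe_p}).to_csv(out / "hwe.tsv", sep="\t", index=False)
    if cfg["qc"]["hwe_alpha"] is not None:
        keep = np.where(hwe_p > cfg["qc"]["hwe_alpha"])[0]
        from .synthetic_data import GenotypeMatrix

        Gf = GenotypeMatrix(Gf.dosages[:, keep], Gf.snp_meta.iloc[keep].reset_index(drop=True),
                            list(Gf.sample_ids))
    log["stages"]["geno_qc"] = {"m_input": G.m, "m_after_maf": Gf.m}

    # 3. trait on the QC'd panel
    table, truth = simulate_trait(
        Gf, pi0=sim["pi0"], effect_sd=sim["effect_sd"], h2=sim["h2"],
        outlier_rate=sim["outlier_rate"], seed=substream(master, "trait"),
    )
    table.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")

    # 4. phenotype QC on the analysis arm
    level = sim["n_level"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        agg = aggregate_phenotype(table, "NUE")
    arm = agg[agg["n_level"] == level].set_index("sample_id").loc[[str(s) for s in Gf.sample_ids]]
    y = arm["value"].to_numpy()
    report = bayesian_bootstrap_normality(y, B=cfg["qc"]["bootstrap_B"],
                                          seed=substream(master, "pheno_qc"))
    report.to_json(out / "normality.json")

    # 5. scan
    K = ibs_kinship(Gf)
    if cfg["scan"]["model"] == "single":
        scan = single_locus_scan(y, Gf, K)
    elif cfg["scan"]["model"] == "multi":
        scan = multi_locus_scan(y, Gf, K, max_steps=cfg["scan"]["max_steps"])
    else:
        raise ValueError("scan.model must be 'single' or 'multi'")
    scan.to_tsv(out / "scan.tsv")

    # 6. linear adjustments
    alpha = cfg["adjust"]["alpha"]
    adj_table = pd.DataFrame({"p_raw": scan.p_raw})
    for method in METHODS:
        adj_table[f"p_adj_{method}"] = adjust(scan.p_raw, method, alpha).p_adj
    adj_table.to_csv(out / "adjusted.tsv", sep="\t", index=False)

    # 7. nonlinear estimates
    z = pvalues_to_z(scan.p_raw)
    pi0 = bootstrap_pi0(scan.p_raw, seed=substream(master, "pi0"))
    q = qvalues(scan.p_raw, pi0)
    try:
        null = empirical_null(z)
    except ValueError:
        null = EmpiricalNull(0.0, 1.0, 1.0)
    fit = local_fdr(z, null, density_df=cfg["fdr"]["density_df"], bins=cfg["fdr"]["bins"])
    pd.DataFrame({"z": z, "qvalue": q, "lfdr": fit.lfdr}).to_csv(out / "fdr.tsv", sep="\t", index=False)
    null.to_json(out / "empirical_null.json")

    # 8. posterior optimization + 9. comparison
    opt = cfg["optimize"]
    comparison = method_comparison(
        scan, truth, alpha=alpha, lfdr_cut=cfg["fdr"]["lfdr_cut"], target_fdr=opt["target_fdr"],
        gibbs_samples=opt["samples"], gibbs_burn_in=opt["burn_in"],
        density_df=cfg["fdr"]["density_df"], bins=cfg["fdr"]["bins"],
        seed=substream(master, "gibbs"),
    )
    comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    post = gibbs_fit(z, n_samples=opt["samples"], burn_in=opt["burn_in"], scale="z",
                     seed=substream(master, "gibbs_trace"))
    post.to_json(out / "posterior.json")
    post.trace_frame().to_csv(out / "trace.tsv", sep="\t", index=False)

    import threshfdr

    log["version"] = threshfdr.__version__
    log["config"] = cfg
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return out
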