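"""End-to-end discovery -> validation -> consensus workflow.

Driven by a single YAML/dict configuration; every stage's seed is derived
from one master seed, so re-running a config reproduces all numeric
outputs bit-identically.  Outputs are TSV tables (regions ranked by
empirical p, per-SNP PIPs with the -log10(1-PIP) Manhattan column,
per-region sum of PIPs, consensus pairs) plus optional plots and a run
log recording every seed and parameter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import genotypes as gio
from . import permutation as perm
from . import regions as reg
from . import synthetic as syn
from .plotting import neg_log10_one_minus, render_manhattan, render_region_sums
from .sampler import BVSConfig, BVSPriors

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


DEFAULT_CONFIG = {
    "master_seed": 0,
    "out_dir": "regionbvs_out",
    "window": 1000,
    "step": 500,
    "priors": {},
    "mcmc": {"n_iter": 100_000, "burn_in": 0.2, "thin": 10, "trait_mode": "binary"},
    "discovery": {"alpha": 0.1, "b_target": 100_000, "batch": 100},
    "validation": {"alpha": 0.05, "b": 1000, "n_candidates": 12},
    "consensus": {
        "top_region_frac": 0.05,
        "top_snp_frac": 0.01,
        "window_bp": 100_000,
        "r2_threshold": 0.2,
    },
    "plots": True,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _validate_config(cfg: dict) -> None:
    for key in ("discovery", "validation"):
        alpha = cfg[key]["alpha"]
        if not 0.0 < alpha < 1.0:
            raise PipelineError(f"{key}.alpha must lie in (0, 1), got {alpha}")
    if cfg["window"] < 2 or not 1 <= cfg["step"] <= cfg["window"]:
        raise PipelineError("invalid window/step")
    if "synthetic" not in cfg and "data" not in cfg:
        raise PipelineError("config needs either a 'synthetic' or a 'data' block")


def _build_layout(spec: list[dict]) -> list[tuple[str, list[syn.BlockSpec]]]:
    layout = []
    for entry in spec:
        blocks = [
            syn.BlockSpec(
                n_snps=int(b["n_snps"]),
                rho=float(b.get("rho", 0.7)),
                maf_range=tuple(b.get("maf_range", (0.05, 0.5))),
            )
            for b in entry["blocks"]
        ]
        layout.append((str(entry["chrom"]), blocks))
    return layout


def _simulate_cohorts(cfg: dict, seeds: np.ndarray):
    """Simulate discovery and validation cohorts sharing one causal truth."""
    s = cfg["synthetic"]
    layout = _build_layout(s["layout"])
    n_disc = int(s["n_subjects"])
    n_val = int(s.get("validation_n_subjects", n_disc))
    bp_start = int(s.get("bp_start", 1_000_000))
    bp_step = int(s.get("bp_step", 5000))

    G_disc = syn.simulate_genotypes(n_disc, layout, bp_start, bp_step, seed=int(seeds[0]))
    y_disc, truth = syn.simulate_phenotype(
        G_disc,
        n_causal=int(s.get("n_causal", 0)),
        per_variant_h=float(s.get("per_variant_h", syn.DEFAULT_PER_VARIANT_H)),
        prevalence=float(s.get("prevalence", 0.5)),
        balanced=bool(s.get("balanced", True)),
        seed=int(seeds[1]),
    )
    if truth.balanced_indices is not None:
        G_disc = G_disc.take_subjects(truth.balanced_indices)
        y_disc = y_disc.take(truth.balanced_indices)

    rate = float(s.get("missing_rate", 0.0))
    if rate > 0:
        G_disc = gio.impute_missing_mean(
            syn.inject_missing(G_disc, rate, seed=int(seeds[2]))
        )

    G_val_full = syn.simulate_genotypes(
        n_val, layout, bp_start, bp_step, seed=int(seeds[3])
    )
    y_val, truth_val = syn.simulate_phenotype(
        G_val_full,
        n_causal=len(truth.causal_indices),
        per_variant_h=float(s.get("per_variant_h", syn.DEFAULT_PER_VARIANT_H)),
        prevalence=float(s.get("prevalence", 0.5)),
        balanced=bool(s.get("balanced", True)),
        seed=int(seeds[4]),
        causal_indices=truth.causal_indices,
    )
    if truth_val.balanced_indices is not None:
        G_val_full = G_val_full.take_subjects(truth_val.balanced_indices)
        y_val = y_val.take(truth_val.balanced_indices)
    keep = float(s.get("platform_keep_fraction", 1.0))
    G_val = syn.make_platform_subset(
        G_val_full, keep, jitter_ids=bool(s.get("jitter_ids", False)),
        seed=int(seeds[5]),
    )
    # LD reference: the full discovery panel (contains every simulated SNP)
    return G_disc, y_disc, truth, G_val, y_val


def _load_cohorts(cfg: dict):
    d = cfg["data"]
    G_disc, y_disc = gio.read_mean_genotype(
        d["discovery"]["genotype"], d["discovery"]["position"],
        d["discovery"]["phenotype"],
    )
    G_disc = gio.orient_minor_allele(gio.impute_missing_mean(G_disc))
    G_val, y_val = gio.read_mean_genotype(
        d["validation"]["genotype"], d["validation"]["position"],
        d["validation"]["phenotype"],
    )
    G_val = gio.orient_minor_allele(gio.impute_missing_mean(G_val))
    return G_disc, y_disc, None, G_val, y_val


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns paths and key results."""
    cfg = _merged(config)
    _validate_config(cfg)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("regionbvs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(cfg: dict, out: Path) -> dict:
    master_seed = int(cfg["master_seed"])
    seeds = np.random.SeedSequence(master_seed).generate_state(12) >> 1
    logger.info("master_seed=%d stage_seeds=%s", master_seed, seeds.tolist())
    logger.info("config=%s", json.dumps(cfg, default=str, sort_keys=True))

    priors = BVSPriors(**cfg["priors"])
    mcmc = dict(cfg["mcmc"])
    mcmc.setdefault("seed", int(seeds[6]))
    bvs_config = BVSConfig(**mcmc)

    # ---- data
    if "synthetic" in cfg:
        G_disc, y_disc, truth, G_val, y_val = _simulate_cohorts(cfg, seeds)
        if truth is not None:
            syn.write_truth(truth, G_disc, out / "truth.tsv")
    else:
        G_disc, y_disc, truth, G_val, y_val = _load_cohorts(cfg)
    logger.info(
        "discovery: %d subjects (%d cases), %d SNPs; validation: %d subjects "
        "(%d cases), %d SNPs",
        G_disc.n_subjects, y_disc.n_cases, G_disc.n_snps,
        G_val.n_subjects, y_val.n_cases, G_val.n_snps,
    )

    # ---- partition
    regions = reg.partition_genome(G_disc, cfg["window"], cfg["step"])
    reg.regions_table(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    logger.info("%d regions across %d chromosomes", len(regions),
                G_disc.snp_meta["chrom"].nunique())

    # ---- initial scan (per-SNP PIPs, observed region statistics)
    scan_disc = cns.single_scan(
        G_disc, regions, y_disc, priors, bvs_config, master_seed=int(seeds[7])
    )
    _write_scan(scan_disc, out, "discovery")

    # ---- discovery permutation test
    disc_cfg = cfg["discovery"]
    observed = {
        (row["chrom"], row["region"]): row["sum_pip"]
        for _, row in scan_disc.per_region.iterrows()
    }
    results, ranked = perm.genomewide_scan(
        G_disc, regions, y_disc, priors, bvs_config,
        B_target=int(disc_cfg["b_target"]), alpha=float(disc_cfg["alpha"]),
        batch=int(disc_cfg["batch"]), master_seed=int(seeds[8]),
        observed_stats=observed,
    )
    ranked.to_csv(out / "discovery_permutation.tsv", sep="\t", index=False)

    # ---- validation of the best-ranked candidate regions
    val_cfg = cfg["validation"]
    n_cand = min(int(val_cfg.get("n_candidates", 12)), len(regions))
    by_label = {(r.chrom, r.rank_on_chrom): r for r in regions}
    cand_rows = ranked.head(n_cand)
    candidates = [
        by_label[(row["chrom"], row["region"])] for _, row in cand_rows.iterrows()
    ]
    val_records = cns.validate_regions(
        candidates, G_val, y_val, priors, bvs_config,
        B=int(val_cfg["b"]), alpha=float(val_cfg["alpha"]),
        master_seed=int(seeds[9]),
    )
    p_vali = {
        (rec.candidate.chrom, rec.candidate.rank_on_chrom): rec
        for rec in val_records
    }

    # ---- combined headline table (Chr, Region, Start, End, Rank, P_disc, P_vali)
    rows = []
    for _, row in ranked.iterrows():
        rec = p_vali.get((row["chrom"], row["region"]))
        rows.append(
            {
                "Chr": row["chrom"],
                "Region": row["region"],
                "Start position": row["start_pos"],
                "End position": row["end_pos"],
                "Rank": row["rank"],
                "P_disc": row["p_disc_text"],
                "P_vali": (
                    rec.result.p_text()
                    if rec is not None and rec.result is not None
                    else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "regions_ranked.tsv", sep="\t", index=False)

    # ---- validation-cohort scan + consensus
    csn_cfg = cfg["consensus"]
    regions_val = reg.partition_genome(G_val, cfg["window"], cfg["step"])
    scan_val = cns.single_scan(
        G_val, regions_val, y_val, priors, bvs_config, master_seed=int(seeds[10])
    )
    _write_scan(scan_val, out, "validation")
    ld_reference = G_disc
    pairs, summary = cns.overlap_consensus(
        scan_disc, scan_val, ld_reference,
        top_region_frac=float(csn_cfg["top_region_frac"]),
        top_snp_frac=float(csn_cfg["top_snp_frac"]),
        window_bp=int(csn_cfg["window_bp"]),
        r2_threshold=float(csn_cfg["r2_threshold"]),
    )
    cns.consensus_table(pairs).to_csv(out / "consensus_pairs.tsv", sep="\t", index=False)
    with open(out / "consensus_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("consensus summary: %s", summary)

    # ---- plots
    if cfg.get("plots", True):
        render_manhattan(
            scan_disc.per_snp, out / "manhattan_discovery.png", "discovery"
        )
        render_manhattan(
            scan_val.per_snp, out / "manhattan_validation.png", "validation"
        )
        render_region_sums(
            scan_disc.per_region, out / "region_sums_discovery.png", "discovery"
        )
        render_region_sums(
            scan_val.per_region, out / "region_sums_validation.png", "validation"
        )

    return {
        "out_dir": out,
        "regions": regions,
        "ranked": ranked,
        "results": results,
        "validation": val_records,
        "consensus_summary": summary,
        "scan_discovery": scan_disc,
        "scan_validation": scan_val,
        "truth": truth,
    }


def _write_scan(scan: cns.ScanResult, out: Path, tag: str) -> None:
    per_snp = scan.per_snp.copy()
    per_snp["neg_log10_one_minus_pip"] = neg_log10_one_minus(
        per_snp["pip"].to_numpy()
    )
    per_snp.to_csv(out / f"per_snp_pip_{tag}.tsv", sep="\t", index=False)
    scan.per_region.to_csv(out / f"region_sum_pip_{tag}.tsv", sep="\t", index=False)
    long = []
    for (chrom, rank), df in scan.region_pips.items():
        d = df.drop(columns=["chrom"]).copy()
        d.insert(0, "region", rank)
        d.insert(0, "chrom", chrom)
        long.append(d)
    pd.concat(long, ignore_index=True).to_csv(
        out / f"region_pips_{tag}.tsv", sep="\t", index=False
    )
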