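"""Cross-cohort validation and LD-based consensus analysis.

Validation re-tests candidate regions in an independent cohort genotyped
on a (generally different) SNP panel: a candidate's base-pair interval is
mapped onto the validation panel, and because the mapped SNP count varies,
the mean of PIPs replaces the sum as the region statistic.  Significance
uses 1000 permutations at alpha = 0.05 corrected for the number of
candidates.

The consensus analysis compares two scans without permutation: the top 5%
of regions by sum of PIPs are selected in each dataset, within each the
top 1% of SNPs by PIP; every selected SNP of one dataset is paired with
all selected SNPs of the other on the same chromosome within 100 kb, and
a pair whose dosage r^2 in a designated reference panel reaches the LD
threshold joins the consensus set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeVector
from .regions import RegionIndex, chromosome_offsets, extract_region
from .permutation import PermutationResult, region_permutation_test
from .sampler import BVSConfig, BVSPriors, BVSResult, run_bvs

logger = logging.getLogger(__name__)


class ConsensusError(ValueError):
    pass


# ---------------------------------------------------------------------------
# single (no-permutation) scan container
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-region and per-SNP PIP summaries of one genome scan."""

    per_region: pd.DataFrame   # chrom, region, start_pos, end_pos, n_snps, sum_pip, mean_pip
    per_snp: pd.DataFrame      # snp_id, chrom, pos, pip (max over covering windows)
    region_pips: dict[tuple[str, int], pd.DataFrame]  # per-region SNP-level pips


def single_scan(
    G: GenotypeMatrix,
    regions: list[RegionIndex],
    y,
    priors: BVSPriors,
    config: BVSConfig,
    master_seed: int = 0,
) -> ScanResult:
    """Run the region sampler once per region (no permutations)."""
    seeds = np.random.SeedSequence(master_seed).generate_state(len(regions)) >> 1
    region_rows = []
    region_pips: dict[tuple[str, int], pd.DataFrame] = {}
    snp_pip = np.zeros(G.n_snps)
    from .regions import region_columns

    for i, rg in enumerate(regions):
        cols = region_columns(G, rg)
        res = run_bvs(
            G.take_snps(cols), y, priors,
            BVSConfig(
                n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin,
                n_chains=1, seed=int(seeds[i]), trait_mode=config.trait_mode,
                step_h=config.step_h, step_log10_pi=config.step_log10_pi,
            ),
        )
        meta = G.snp_meta.iloc[cols]
        region_pips[(rg.chrom, rg.rank_on_chrom)] = pd.DataFrame(
            {
                "snp_id": meta["snp_id"].to_numpy(),
                "chrom": meta["chrom"].to_numpy(),
                "pos": meta["pos"].to_numpy(),
                "pip": res.pip,
            }
        )
        np.maximum.at(snp_pip, cols, res.pip)
        region_rows.append(
            {
                "chrom": rg.chrom,
                "region": rg.rank_on_chrom,
                "start_pos": rg.start_pos,
                "end_pos": rg.end_pos,
                "n_snps": rg.n_snps,
                "sum_pip": res.sum_pip,
                "mean_pip": res.mean_pip,
            }
        )
    per_snp = pd.DataFrame(
        {
            "snp_id": G.snp_meta["snp_id"].to_numpy(),
            "chrom": G.snp_meta["chrom"].to_numpy(),
            "pos": G.snp_meta["pos"].to_numpy(),
            "pip": snp_pip,
        }
    )
    return ScanResult(
        per_region=pd.DataFrame(region_rows), per_snp=per_snp,
        region_pips=region_pips,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def map_region_to_validation(
    region: RegionIndex, validation_meta: pd.DataFrame
) -> RegionIndex | None:
    """Map a discovery region onto the validation SNP panel by position.

    Returns the validation-panel region covering the same base-pair
    interval (both ends inclusive), or None (with a warning) when the
    chromosome is absent or no validation SNP falls inside the interval.
    """
    chroms = validation_meta["chrom"].astype(str).to_numpy()
    on = np.where(chroms == str(region.chrom))[0]
    if on.size == 0:
        logger.warning(
            "chromosome %s absent from validation panel", region.chrom
        )
        return None
    pos = validation_meta["pos"].to_numpy()[on]
    if np.any(np.diff(pos) <= 0):
        raise ConsensusError("validation SNPs must be sorted by (chrom, pos)")
    lo = int(np.searchsorted(pos, region.start_pos, side="left"))
    hi = int(np.searchsorted(pos, region.end_pos, side="right"))
    if lo >= hi:
        logger.warning(
            "no validation SNPs inside %s:[%d, %d]",
            region.chrom, region.start_pos, region.end_pos,
        )
        return None
    return RegionIndex(
        chrom=region.chrom,
        rank_on_chrom=region.rank_on_chrom,
        start=lo,
        stop=hi,
        start_pos=int(pos[lo]),
        end_pos=int(pos[hi - 1]),
    )


@dataclass
class ValidationRecord:
    """One candidate region's validation outcome."""

    candidate: RegionIndex
    mapped: RegionIndex | None
    result: PermutationResult | None
    validated: bool
    reason: str | None = None


def validate_regions(
    candidates: list[RegionIndex],
    G_val: GenotypeMatrix,
    y_val: PhenotypeVector,
    priors: BVSPriors,
    config: BVSConfig,
    B: int = 1000,
    alpha: float = 0.05,
    master_seed: int = 0,
    stop_early: bool = True,
) -> list[ValidationRecord]:
    """Permutation-test candidates on the validation cohort (mean of PIPs).

    alpha is corrected by the number of candidates undergoing validation.
    """
    if not candidates:
        raise ConsensusError("no candidate regions to validate")
    alpha_adj = alpha / len(candidates)
    records = []
    for cand in candidates:
        mapped = map_region_to_validation(cand, G_val.snp_meta)
        if mapped is None:
            records.append(
                ValidationRecord(
                    candidate=cand, mapped=None, result=None,
                    validated=False, reason="no SNPs in validation interval",
                )
            )
            continue
        res = region_permutation_test(
            extract_region(G_val, mapped),
            y_val,
            priors,
            config,
            B_target=B,
            alpha_adj=alpha_adj,
            batch=min(100, B),
            master_seed=master_seed,
            region=mapped,
            statistic="mean_pip",
            stop_early=stop_early,
        )
        records.append(
            ValidationRecord(
                candidate=cand, mapped=mapped, result=res,
                validated=res.significant,
            )
        )
    return records


# ---------------------------------------------------------------------------
# LD and consensus
# ---------------------------------------------------------------------------

def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float).ravel()
    b = np.asarray(dosage_b, dtype=float).ravel()
    if a.size != b.size:
        raise ConsensusError("dosage vectors differ in length")
    if a.size < 3:
        raise ConsensusError("need at least 3 subjects for LD")
    if a.std() == 0 or b.std() == 0:
        raise ConsensusError("constant dosage vector has undefined LD")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ConsensusPair:
    """One cross-dataset pair of top SNPs within the pairing window."""

    snp_a: str
    snp_b: str
    chrom: str
    distance_bp: int
    r2: float          # NaN when either SNP is absent from the reference
    in_ld: bool


def _top_snp_table(
    scan: ScanResult, top_region_frac: float, top_snp_frac: float
) -> pd.DataFrame:
    """Top-PIP SNPs of the top-sum-PIP regions of one scan."""
    per_region = scan.per_region
    n_sel = math.ceil(top_region_frac * len(per_region))
    # ties in sum_pip broken by genome order (stable sort on descending key)
    order = np.argsort(-per_region["sum_pip"].to_numpy(), kind="stable")[:n_sel]
    frames = []
    for i in order:
        row = per_region.iloc[i]
        pips = scan.region_pips[(row["chrom"], row["region"])]
        k = math.ceil(top_snp_frac * len(pips))
        snp_order = np.argsort(-pips["pip"].to_numpy(), kind="stable")[:k]
        frames.append(pips.iloc[snp_order])
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(subset="snp_id").reset_index(drop=True)


def overlap_consensus(
    scan_A: ScanResult,
    scan_B: ScanResult,
    ld_reference: GenotypeMatrix,
    top_region_frac: float = 0.05,
    top_snp_frac: float = 0.01,
    window_bp: int = 100_000,
    r2_threshold: float = 0.2,
) -> tuple[list[ConsensusPair], dict]:
    """Cross-dataset overlap and LD consensus of two scans.

    Every selected SNP of A pairs with all selected SNPs of B on the same
    chromosome within ``window_bp`` (symmetric; duplicates merged).  LD is
    computed in ``ld_reference``; pairs missing from the reference are
    reported with r2 = NaN and excluded from the percentage denominator.
    The summary reports the fraction of overlap pairs in LD.
    """
    top_a = _top_snp_table(scan_A, top_region_frac, top_snp_frac)
    top_b = _top_snp_table(scan_B, top_region_frac, top_snp_frac)
    ref_idx = {s: j for j, s in enumerate(ld_reference.snp_meta["snp_id"])}
    # allow position-based lookup too (platforms may rename SNPs)
    pos_idx = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(
            zip(ld_reference.snp_meta["chrom"], ld_reference.snp_meta["pos"])
        )
    }

    def ref_col(snp_id: str, chrom: str, pos: int) -> int | None:
        if snp_id in ref_idx:
            return ref_idx[snp_id]
        return pos_idx.get((str(chrom), int(pos)))

    pairs: dict[tuple[str, str], ConsensusPair] = {}
    b_by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("pos") for c, g in top_b.groupby("chrom")
    }
    n_missing = 0
    for _, ra in top_a.iterrows():
        grp = b_by_chrom.get(str(ra["chrom"]))
        if grp is None:
            continue
        pos_b = grp["pos"].to_numpy()
        lo = np.searchsorted(pos_b, ra["pos"] - window_bp, side="left")
        hi = np.searchsorted(pos_b, ra["pos"] + window_bp, side="right")
        for _, rb in grp.iloc[lo:hi].iterrows():
            key = (str(ra["snp_id"]), str(rb["snp_id"]))
            if key in pairs:
                continue
            ja = ref_col(ra["snp_id"], ra["chrom"], ra["pos"])
            jb = ref_col(rb["snp_id"], rb["chrom"], rb["pos"])
            if ja is None or jb is None:
                n_missing += 1
                logger.warning("pair %s lacks LD reference dosages", key)
                r2 = float("nan")
                in_ld = False
            elif ja == jb:
                r2 = 1.0
                in_ld = True
            else:
                r2 = ld_r2(
                    ld_reference.dosages[:, ja], ld_reference.dosages[:, jb]
                )
                in_ld = r2 >= r2_threshold
            pairs[key] = ConsensusPair(
                snp_a=key[0],
                snp_b=key[1],
                chrom=str(ra["chrom"]),
                distance_bp=int(abs(int(ra["pos"]) - int(rb["pos"]))),
                r2=r2,
                in_ld=in_ld,
            )
    pair_list = sorted(
        pairs.values(), key=lambda p: (p.chrom, p.snp_a, p.snp_b)
    )
    with_r2 = [p for p in pair_list if not math.isnan(p.r2)]
    n_in_ld = sum(p.in_ld for p in with_r2)
    summary = {
        "n_pairs": len(pair_list),
        "n_with_r2": len(with_r2),
        "n_in_ld": n_in_ld,
        "pct_in_ld": (100.0 * n_in_ld / len(with_r2)) if with_r2 else float("nan"),
        "n_missing_reference": n_missing,
    }
    return pair_list, summary


def consensus_table(pairs: list[ConsensusPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_a": [p.snp_a for p in pairs],
            "snp_b": [p.snp_b for p in pairs],
            "chrom": [p.chrom for p in pairs],
            "distance_bp": [p.distance_bp for p in pairs],
            "r2": [p.r2 for p in pairs],
            "in_ld": [p.in_ld for p in pairs],
        }
    )
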