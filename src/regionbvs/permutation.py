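"""Region-level permutation significance with early stopping.

The observed region statistic (sum of PIPs in discovery, mean of PIPs in
validation) is compared with its distribution under random relabelling of
case/control status.  Each permutation reruns the full region sampler on
the permuted phenotype with a seed derived deterministically from
(master_seed, region, permutation index), so results are reproducible and
independent of batching.

The empirical p-value is r/B, where r counts permuted statistics greater
than or equal to the observed one (ties count against significance).
Permutations for a region stop early once significance has become
impossible: if already r / B_target > alpha, the final p-value would
exceed alpha even if no further exceedance occurred, so the early-stop
decision always agrees with the exhaustive run.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeVector
from .regions import RegionIndex, extract_region
from .sampler import BVSConfig, BVSPriors, RegionRunner

logger = logging.getLogger(__name__)


class PermutationError(ValueError):
    pass


@dataclass
class PermutationResult:
    """Outcome of one region's permutation test."""

    region: RegionIndex | None
    statistic: str                 # "sum_pip" or "mean_pip"
    observed_stat: float
    B_target: int
    B_done: int
    r: int
    p_emp: float
    stopped_early: bool
    significant: bool
    alpha_adj: float

    def p_text(self) -> str:
        return format_empirical_p(self.r, self.B_done)


def bonferroni_threshold(alpha: float, n_regions: int) -> float:
    """Family-wise threshold alpha / n_regions."""
    if not 0.0 < alpha <= 1.0:
        raise PermutationError(f"alpha must lie in (0, 1], got {alpha}")
    if n_regions < 1:
        raise PermutationError("n_regions must be >= 1")
    return alpha / n_regions


def permute_phenotype(y: PhenotypeVector, rng: np.random.Generator) -> PhenotypeVector:
    """Uniformly random relabelling; the case count is preserved exactly."""
    return PhenotypeVector(rng.permutation(y.labels))


def empirical_p(r: int, B: int, estimator: str = "plain") -> float:
    """Empirical p-value from r exceedances in B permutations.

    ``plain`` returns r/B (0 is reported textually as "<1/B");
    ``add_one`` returns (r+1)/(B+1), strictly positive.
    """
    if B < 1:
        raise PermutationError("B must be >= 1")
    if not 0 <= r <= B:
        raise PermutationError(f"require 0 <= r <= B, got r={r}, B={B}")
    if estimator == "plain":
        return r / B
    if estimator == "add_one":
        return (r + 1) / (B + 1)
    raise PermutationError(f"unknown estimator {estimator!r}")


def format_empirical_p(r: int, B: int, estimator: str = "plain") -> str:
    """Text form of the empirical p; r=0 under ``plain`` prints "<1/B"."""
    p = empirical_p(r, B, estimator)
    if estimator == "plain" and r == 0:
        return f"<{1.0 / B:.3g}"
    return f"{p:.3g}"


def _perm_seed(master_seed: int, region: RegionIndex | None, b: int) -> np.random.SeedSequence:
    """Deterministic per-permutation seed stream; b = 0 is the observed run,
    permutation i uses b = i + 1."""
    key = zlib.crc32(
        f"{region.chrom}:{region.rank_on_chrom}".encode() if region else b"genome"
    )
    return np.random.SeedSequence((int(master_seed), key, int(b) + 1))


def region_permutation_test(
    G_region,
    y: PhenotypeVector,
    priors: BVSPriors,
    config: BVSConfig,
    B_target: int = 100_000,
    alpha_adj: float = 0.1 / 1266,
    batch: int = 100,
    master_seed: int = 0,
    region: RegionIndex | None = None,
    statistic: str = "sum_pip",
    stop_early: bool = True,
    observed_stat: float | None = None,
) -> PermutationResult:
    """Permutation test of one region's association statistic.

    ``observed_stat`` may be supplied when the unpermuted scan has already
    been run (e.g. by a genome-wide driver); otherwise it is computed here
    from the unpermuted phenotype.
    """
    if B_target < 1:
        raise PermutationError("B_target must be >= 1")
    if not 0.0 < alpha_adj < 1.0:
        raise PermutationError("alpha_adj must lie in (0, 1)")
    if statistic not in {"sum_pip", "mean_pip"}:
        raise PermutationError(f"unknown region statistic {statistic!r}")
    if batch < 1:
        raise PermutationError("batch must be >= 1")

    runner = RegionRunner(G_region, priors, config)
    if observed_stat is None:
        obs_seed = int(
            _perm_seed(master_seed, region, -1).generate_state(1)[0] >> 1
        )
        observed_stat = runner.stat(y, obs_seed, statistic)

    r = 0
    b_done = 0
    stopped = False
    while b_done < B_target:
        todo = min(batch, B_target - b_done)
        for i in range(todo):
            ss = _perm_seed(master_seed, region, b_done + i)
            rng = np.random.default_rng(ss)
            y_perm = permute_phenotype(y, rng)
            seed_b = int(ss.generate_state(2)[1] >> 1)
            stat = runner.stat(y_perm, seed_b, statistic)
            if stat >= observed_stat:
                r += 1
        b_done += todo
        # even if no further permutation exceeded, final p would be > alpha
        if stop_early and b_done < B_target and r / B_target > alpha_adj:
            stopped = True
            break
    p = empirical_p(r, b_done)
    significant = (not stopped) and p <= alpha_adj
    return PermutationResult(
        region=region,
        statistic=statistic,
        observed_stat=float(observed_stat),
        B_target=B_target,
        B_done=b_done,
        r=r,
        p_emp=p,
        stopped_early=stopped,
        significant=significant,
        alpha_adj=alpha_adj,
    )


def _genome_rank_key(regions: list[RegionIndex]) -> dict[tuple[str, int], int]:
    return {(rg.chrom, rg.rank_on_chrom): i for i, rg in enumerate(regions)}


def rank_results(
    results: list[PermutationResult], regions: list[RegionIndex]
) -> pd.DataFrame:
    """Rank regions by empirical p, ties broken by observed statistic
    (larger first) then genome order."""
    order_key = _genome_rank_key(regions)
    idx = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].p_emp,
            -results[i].observed_stat,
            order_key[(results[i].region.chrom, results[i].region.rank_on_chrom)],
        ),
    )
    rows = []
    for rank, i in enumerate(idx, start=1):
        res = results[i]
        rows.append(
            {
                "chrom": res.region.chrom,
                "region": res.region.rank_on_chrom,
                "start_pos": res.region.start_pos,
                "end_pos": res.region.end_pos,
                "rank": rank,
                "p_disc": res.p_emp,
                "p_disc_text": res.p_text(),
                "observed_stat": res.observed_stat,
                "r": res.r,
                "B_done": res.B_done,
                "stopped_early": res.stopped_early,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def genomewide_scan(
    G: GenotypeMatrix,
    regions: list[RegionIndex],
    y: PhenotypeVector,
    priors: BVSPriors,
    config: BVSConfig,
    B_target: int = 100_000,
    alpha: float = 0.1,
    batch: int = 100,
    master_seed: int = 0,
    stop_early: bool = True,
    observed_stats: dict[tuple[str, int], float] | None = None,
) -> tuple[list[PermutationResult], pd.DataFrame]:
    """Permutation-test every region; returns results plus a ranked table.

    The family-wise threshold is ``alpha / len(regions)`` (Bonferroni).
    ``observed_stats`` may carry precomputed sum-of-PIP statistics keyed by
    (chrom, rank_on_chrom).
    """
    if not regions:
        raise PermutationError("no regions to scan")
    alpha_adj = bonferroni_threshold(alpha, len(regions))
    results = []
    for rg in regions:
        obs = None
        if observed_stats is not None:
            obs = observed_stats.get((rg.chrom, rg.rank_on_chrom))
        res = region_permutation_test(
            extract_region(G, rg),
            y,
            priors,
            config,
            B_target=B_target,
            alpha_adj=alpha_adj,
            batch=batch,
            master_seed=master_seed,
            region=rg,
            statistic="sum_pip",
            stop_early=stop_early,
            observed_stat=obs,
        )
        logger.info(
            "region %s: stat=%.3f r=%d B=%d p=%s%s",
            rg.label, res.observed_stat, res.r, res.B_done, res.p_text(),
            " (early stop)" if res.stopped_early else "",
        )
        results.append(res)
    return results, rank_results(results, regions)
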