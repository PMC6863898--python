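"""Sliding-window partition of each chromosome's ordered SNPs.

Chromosomes are cut into windows of a fixed number of SNPs (default 1000)
that slide by ``step`` SNPs (default half a window, giving 50% overlap so
nearby SNPs are always co-modelled in at least one window).  Window ends
are handled so every full-chromosome window has equal size: the final
window is anchored to the last ``window`` SNPs whenever a stepped start
would leave trailing SNPs uncovered; chromosomes shorter than one window
form a single all-SNP region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class RegionIndex:
    """One sliding window on one chromosome.

    ``start``/``stop`` are a half-open index range into that chromosome's
    ordered SNP list; ``start_pos``/``end_pos`` are the base-pair positions
    of the first and last included SNP (both ends inclusive).
    Regions are numbered per chromosome starting from 1.
    """

    chrom: str
    rank_on_chrom: int
    start: int
    stop: int
    start_pos: int
    end_pos: int

    @property
    def n_snps(self) -> int:
        return self.stop - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.rank_on_chrom}"


def partition_chromosome(
    n_snps_on_chrom: int, window: int = 1000, step: int | None = None
) -> list[tuple[int, int]]:
    """Return half-open (start, stop) spans for one chromosome.

    Starts run 0, step, 2*step, ...; if the last stepped window does not
    reach the chromosome end, a final window anchored to the last
    ``window`` SNPs is appended.  Short chromosomes yield one span of all
    SNPs.
    """
    if n_snps_on_chrom <= 0:
        raise PartitionError("chromosome has no SNPs")
    if window < 2:
        raise PartitionError("window must be >= 2")
    if step is None:
        step = window // 2
    if not 1 <= step <= window:
        raise PartitionError(f"step must be in [1, window], got {step}")
    if n_snps_on_chrom <= window:
        return [(0, n_snps_on_chrom)]
    spans: list[tuple[int, int]] = []
    s = 0
    while s + window <= n_snps_on_chrom:
        spans.append((s, s + window))
        s += step
    if spans[-1][1] < n_snps_on_chrom:
        anchored = (n_snps_on_chrom - window, n_snps_on_chrom)
        if anchored != spans[-1]:
            spans.append(anchored)
    return spans


def chromosome_offsets(G: GenotypeMatrix) -> dict[str, tuple[int, int]]:
    """Map chromosome label -> (first, last+1) global column index in G."""
    chroms = G.snp_meta["chrom"].to_numpy()
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            if chroms[start] in offsets:
                raise PartitionError(
                    f"SNPs of chromosome {chroms[start]} are not contiguous; "
                    "sort snp_meta by (chrom, pos) first"
                )
            offsets[chroms[start]] = (start, i)
            start = i
    return offsets


def partition_genome(
    G: GenotypeMatrix, window: int = 1000, step: int | None = None
) -> list[RegionIndex]:
    """Partition every chromosome of ``G``; regions in genome order."""
    if G.n_snps == 0:
        raise PartitionError("genotype matrix has no SNPs")
    pos = G.snp_meta["pos"].to_numpy()
    regions: list[RegionIndex] = []
    for chrom, (lo, hi) in chromosome_offsets(G).items():
        if np.any(np.diff(pos[lo:hi]) <= 0):
            raise PartitionError(f"chromosome {chrom} positions unsorted")
        for rank, (a, b) in enumerate(
            partition_chromosome(hi - lo, window, step), start=1
        ):
            regions.append(
                RegionIndex(
                    chrom=str(chrom),
                    rank_on_chrom=rank,
                    start=a,
                    stop=b,
                    start_pos=int(pos[lo + a]),
                    end_pos=int(pos[lo + b - 1]),
                )
            )
    return regions


def region_columns(G: GenotypeMatrix, region: RegionIndex) -> np.ndarray:
    """Global column indices of ``region``'s SNPs in ``G``."""
    lo, hi = chromosome_offsets(G)[region.chrom]
    if region.stop > hi - lo:
        raise PartitionError(
            f"region {region.label} span exceeds chromosome {region.chrom}"
        )
    return np.arange(lo + region.start, lo + region.stop)


def extract_region(G: GenotypeMatrix, region: RegionIndex) -> GenotypeMatrix:
    """Subset ``G`` to the SNP columns of ``region``."""
    return G.take_snps(region_columns(G, region))


def regions_table(regions: list[RegionIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "region": [r.rank_on_chrom for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "start_pos": [r.start_pos for r in regions],
            "end_pos": [r.end_pos for r in regions],
        }
    )
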