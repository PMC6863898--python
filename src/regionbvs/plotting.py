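"""Report plots: Manhattan-style PIP plot and per-region sum-of-PIP plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

#: PIPs are clipped at 1 - 1e-6 before the log transform to avoid infinities.
PIP_CLIP = 1.0 - 1e-6


def neg_log10_one_minus(pip: np.ndarray) -> np.ndarray:
    """Manhattan y-axis transform -log10(1 - PIP), clipped near PIP = 1."""
    p = np.clip(np.asarray(pip, dtype=float), 0.0, PIP_CLIP)
    return -np.log10(1.0 - p)


def _chrom_order(chroms) -> list[str]:
    def key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    return sorted(dict.fromkeys(str(c) for c in chroms), key=key)


def render_manhattan(per_snp: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Genome-ordered scatter of -log10(1 - PIP) with alternating shading."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(_chrom_order(per_snp["chrom"])):
        sub = per_snp[per_snp["chrom"].astype(str) == chrom].sort_values("pos")
        x = offset + np.arange(len(sub))
        ax.scatter(
            x, neg_log10_one_minus(sub["pip"].to_numpy()),
            s=4, color="#1f77b4" if i % 2 == 0 else "#ff7f0e", linewidths=0,
        )
        ticks.append(offset + len(sub) / 2)
        labels.append(chrom)
        offset += len(sub)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(1-\mathrm{PIP})$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_region_sums(per_region: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Per-region sum-of-PIPs in genome order."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(_chrom_order(per_region["chrom"])):
        sub = per_region[per_region["chrom"].astype(str) == chrom].sort_values("region")
        x = offset + np.arange(len(sub))
        ax.vlines(x, 0, sub["sum_pip"].to_numpy(),
                  color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
        ticks.append(offset + len(sub) / 2)
        labels.append(chrom)
        offset += len(sub)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("sum of PIPs")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
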