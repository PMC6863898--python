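"""Synthetic case-control genotype data with LD-block structure.

The generator emulates the statistical features the region-based analysis
assumes: 0/1/2 minor-allele dosages, linkage-disequilibrium blocks,
missing genotypes, a liability-threshold binary phenotype with many tiny
effects, and a second genotyping "platform" carrying a partially
overlapping SNP panel.

Haplotypes come from a Gaussian copula: within a block, each haplotype's
latent values share an exchangeable correlation ``rho`` and an allele is
minor when its latent value falls below the normal quantile of that SNP's
minor-allele frequency.  A subject's dosage is the sum of two independent
haplotypes, so dosage correlation within a block has the closed form

    r = (Phi2(t, t; rho) - maf^2) / (maf (1 - maf)),  t = Phi^{-1}(maf),

which the tests use as an oracle.  Blocks are mutually independent.

The phenotype is a liability-threshold model: each causal SNP j
contributes beta_j * standardized dosage to a latent liability with unit
residual noise, with beta_j set so that SNP j explains exactly
``per_variant_h`` of the liability variance.  The default per-variant
fraction is 0.0017, the scale expected when ~18% of variance is spread
over ~100 loci of a highly polygenic trait.  Cases are subjects whose
liability exceeds the empirical quantile matching the prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .genotypes import GenotypeError, GenotypeMatrix, PhenotypeVector, orient_minor_allele

#: Per-causal-variant fraction of liability variance (0.184 / 108).
DEFAULT_PER_VARIANT_H = 0.0017


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: SNP count, latent exchangeable correlation, MAF range."""

    n_snps: int
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("block must contain at least one SNP")
        if not 0.0 <= self.rho < 1.0:
            raise SimulationError(f"rho must lie in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated phenotype."""

    causal_indices: np.ndarray
    effects: np.ndarray
    per_variant_h: np.ndarray
    prevalence: float
    liability: np.ndarray | None = None
    balanced_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        self.per_variant_h = np.asarray(self.per_variant_h, dtype=float)
        if len(self.effects) != len(self.causal_indices):
            raise SimulationError("one effect per causal index required")
        if np.any((self.per_variant_h < 0) | (self.per_variant_h >= 1)):
            raise SimulationError("per_variant_h entries must lie in [0, 1)")
        if self.per_variant_h.sum() >= 1:
            raise SimulationError("total per-variant variance must be < 1")


def simulate_genotypes(
    n_subjects: int,
    layout: list[tuple[str, list[BlockSpec]]],
    bp_start: int = 1_000_000,
    bp_step: int = 5000,
    seed: int = 0,
    ar1: bool = False,
) -> GenotypeMatrix:
    """Simulate dosages for a chromosome layout of LD blocks.

    ``layout`` is a list of (chromosome label, blocks).  Positions start at
    ``bp_start`` on each chromosome and advance by ``bp_step``.  With
    ``ar1`` the within-block latent correlation decays as rho^|i-j|
    instead of being exchangeable.
    """
    if n_subjects < 2:
        raise SimulationError("need at least 2 subjects")
    if not layout:
        raise SimulationError("empty chromosome layout")
    chroms = [c for c, _ in layout]
    if len(set(chroms)) != len(chroms):
        raise SimulationError("chromosome labels must be distinct")
    if bp_step < 1:
        raise SimulationError("bp_step must be >= 1")
    rng = np.random.default_rng(seed)

    cols = []
    meta_rows = []
    for chrom, blocks in layout:
        if not blocks:
            raise SimulationError(f"chromosome {chrom} has no blocks")
        pos = bp_start
        idx_on_chrom = 0
        for blk in blocks:
            m = blk.n_snps
            mafs = rng.uniform(blk.maf_range[0], blk.maf_range[1], size=m)
            thresholds = ndtri(mafs)
            # two haplotypes per subject, latent Gaussian per block
            if ar1 and m > 1:
                lat = np.empty((2 * n_subjects, m))
                lat[:, 0] = rng.standard_normal(2 * n_subjects)
                a = np.sqrt(1.0 - blk.rho**2)
                for j in range(1, m):
                    lat[:, j] = blk.rho * lat[:, j - 1] + a * rng.standard_normal(
                        2 * n_subjects
                    )
            else:
                shared = rng.standard_normal((2 * n_subjects, 1))
                lat = np.sqrt(blk.rho) * shared + np.sqrt(1.0 - blk.rho) * (
                    rng.standard_normal((2 * n_subjects, m))
                )
            alleles = (lat <= thresholds).astype(np.float64)
            dos = alleles[: n_subjects] + alleles[n_subjects :]
            cols.append(dos)
            for _ in range(m):
                meta_rows.append(
                    {
                        "snp_id": f"snp_{chrom}_{idx_on_chrom:06d}",
                        "chrom": str(chrom),
                        "pos": pos,
                        "minor": "A",
                        "major": "G",
                    }
                )
                pos += bp_step
                idx_on_chrom += 1
    G = GenotypeMatrix(
        dosages=np.hstack(cols),
        snp_meta=pd.DataFrame(meta_rows),
        subject_ids=np.array([f"ind{i}" for i in range(n_subjects)]),
    )
    return orient_minor_allele(G)


def simulate_phenotype(
    G: GenotypeMatrix,
    n_causal: int,
    per_variant_h: float = DEFAULT_PER_VARIANT_H,
    prevalence: float = 0.5,
    balanced: bool = False,
    seed: int = 0,
    causal_indices: np.ndarray | None = None,
) -> tuple[PhenotypeVector, SyntheticTruth]:
    """Liability-threshold phenotype over ``G``'s subjects.

    Each causal SNP explains exactly ``per_variant_h`` of the liability
    variance by construction (effects placed on standardized dosages).
    Cases are subjects above the empirical liability quantile at
    1 - prevalence.  With ``balanced``, ``truth.balanced_indices`` holds a
    case/control-balanced subject subset (all of the minority class plus
    an equally sized random draw of the majority class).
    """
    if not 0.0 < prevalence < 1.0:
        raise SimulationError("prevalence must lie in (0, 1)")
    if per_variant_h < 0 or per_variant_h >= 1:
        raise SimulationError("per_variant_h must lie in [0, 1)")
    if n_causal > G.n_snps:
        raise SimulationError("more causal SNPs requested than SNPs available")
    if n_causal * per_variant_h >= 1:
        raise SimulationError("total variance explained must be < 1")
    if G.has_missing:
        raise GenotypeError("simulate_phenotype requires complete dosages")
    rng = np.random.default_rng(seed)
    n = G.n_subjects

    if causal_indices is None:
        if n_causal > 0:
            sd = G.dosages.std(axis=0)
            poly = np.where(sd > 0)[0]
            if len(poly) < n_causal:
                raise SimulationError("not enough polymorphic SNPs for causal set")
            causal_indices = np.sort(rng.choice(poly, size=n_causal, replace=False))
        else:
            causal_indices = np.array([], dtype=int)
    else:
        causal_indices = np.sort(np.asarray(causal_indices, dtype=int))
        n_causal = len(causal_indices)

    if n_causal > 0:
        beta = np.full(
            n_causal,
            np.sqrt(per_variant_h / (1.0 - n_causal * per_variant_h)),
        )
        Xc = G.dosages[:, causal_indices]
        sd = Xc.std(axis=0)
        if np.any(sd == 0):
            raise SimulationError("causal SNP with zero dosage variance")
        Xs = (Xc - Xc.mean(axis=0)) / sd
        genetic = Xs @ beta
    else:
        beta = np.array([], dtype=float)
        genetic = np.zeros(n)
    liability = genetic + rng.standard_normal(n)
    threshold = np.quantile(liability, 1.0 - prevalence)
    labels = (liability > threshold).astype(np.int8)
    if labels.sum() in (0, n):  # extreme prevalence at tiny n
        raise SimulationError("prevalence too extreme for the sample size")

    balanced_idx = None
    if balanced:
        cases = np.where(labels == 1)[0]
        controls = np.where(labels == 0)[0]
        k = min(len(cases), len(controls))
        big, small = (cases, controls) if len(cases) > len(controls) else (controls, cases)
        chosen = rng.choice(big, size=k, replace=False)
        balanced_idx = np.sort(np.concatenate([small, chosen]))

    truth = SyntheticTruth(
        causal_indices=causal_indices,
        effects=beta,
        per_variant_h=np.full(n_causal, per_variant_h),
        prevalence=prevalence,
        liability=liability,
        balanced_indices=balanced_idx,
    )
    return PhenotypeVector(labels), truth


def inject_missing(
    G: GenotypeMatrix, rate: float, seed: int = 0, max_redraws: int = 10
) -> GenotypeMatrix:
    """Mask each dosage independently with probability ``rate``.

    Columns that end up fully masked are redrawn up to ``max_redraws``
    times; if a column still has no observed entry the input is rejected
    (mean imputation would be impossible).
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return GenotypeMatrix(
            dosages=G.dosages.copy(),
            snp_meta=G.snp_meta.copy(),
            subject_ids=G.subject_ids.copy(),
            missing_mask=None if G.missing_mask is None else G.missing_mask.copy(),
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(G.dosages.shape) < rate
    for _ in range(max_redraws):
        full = mask.all(axis=0)
        if not full.any():
            break
        mask[:, full] = rng.random((G.n_subjects, int(full.sum()))) < rate
    if mask.all(axis=0).any():
        j = int(np.argmax(mask.all(axis=0)))
        raise SimulationError(
            f"could not keep an observed genotype in SNP column "
            f"{G.snp_meta['snp_id'].iloc[j]!r} at rate {rate}"
        )
    dos = G.dosages.copy()
    dos[mask] = np.nan
    return GenotypeMatrix(
        dosages=dos,
        snp_meta=G.snp_meta.copy(),
        subject_ids=G.subject_ids.copy(),
        missing_mask=mask,
    )


def make_platform_subset(
    G: GenotypeMatrix,
    keep_fraction: float,
    jitter_ids: bool = False,
    seed: int = 0,
) -> GenotypeMatrix:
    """Uniformly subsample SNP columns, emulating a second genotyping chip.

    Positions are unchanged and column order preserved.  ``jitter_ids``
    renames SNPs (platforms use their own identifiers); positions remain
    the cross-platform join key.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise SimulationError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = int(round(keep_fraction * G.n_snps))
    if n_keep == 0:
        raise SimulationError("keep_fraction leaves an empty SNP panel")
    idx = np.sort(rng.choice(G.n_snps, size=n_keep, replace=False))
    sub = G.take_snps(idx)
    if jitter_ids:
        meta = sub.snp_meta.copy()
        meta["snp_id"] = [f"alt_{s}" for s in meta["snp_id"]]
        sub = GenotypeMatrix(
            dosages=sub.dosages,
            snp_meta=meta,
            subject_ids=sub.subject_ids,
            missing_mask=sub.missing_mask,
        )
    return sub


def write_truth(truth: SyntheticTruth, G: GenotypeMatrix, path: str | Path) -> None:
    """Write the causal-SNP truth table (snp_id, effect, per_variant_h)."""
    ids = G.snp_meta["snp_id"].to_numpy()[truth.causal_indices]
    pd.DataFrame(
        {
            "snp_id": ids,
            "effect": truth.effects,
            "per_variant_h": truth.per_variant_h,
        }
    ).to_csv(path, sep="\t", index=False)


def expected_dosage_r(maf: float, rho: float) -> float:
    """Closed-form within-block dosage correlation of the copula model."""
    from scipy.stats import multivariate_normal

    t = ndtri(maf)
    p11 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
        [t, t]
    )
    return (p11 - maf**2) / (maf * (1.0 - maf))


def expected_case_control_dosage_diff(
    maf: float, per_variant_h: float, prevalence: float
) -> float:
    """Oracle for the case-control mean dosage gap at one causal SNP.

    Integrates the liability model over the Hardy-Weinberg genotype
    distribution: P(case | g) = Phi(beta * x_g - t) with the threshold t
    solving for the target prevalence.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    pg = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    g = np.array([0.0, 1.0, 2.0])
    mean = 2 * maf
    sd = np.sqrt(2 * maf * (1 - maf))
    x = (g - mean) / sd
    beta = np.sqrt(per_variant_h / (1.0 - per_variant_h))

    def case_prob(t):
        return float(pg @ norm.sf(t - beta * x)) - prevalence

    t = brentq(case_prob, -10, 10)
    p_case_g = norm.sf(t - beta * x)
    p_case = float(pg @ p_case_g)
    e_case = float((pg * p_case_g) @ g) / p_case
    e_ctrl = float((pg * (1 - p_case_g)) @ g) / (1 - p_case)
    return e_case - e_ctrl
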