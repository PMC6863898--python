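"""Genotype/phenotype containers and text-format I/O.

Dosages are stored as an ``n_subjects x n_snps`` float matrix with values
in [0, 2], counting copies of the *minor* allele.  Missing entries are held
as NaN and mirrored in ``missing_mask``; :func:`impute_missing_mean`
replaces them by the per-SNP observed mean, the standard preprocessing for
mean-genotype ("BIMBAM"/piMASS-style) input files.

Two text dialects are supported:

* mean-genotype triplet: a genotype file with one SNP per row
  (``snp_id, minor_allele, major_allele, dosage_1 ... dosage_n``), a
  position file (``snp_id, bp, chrom``) and a phenotype file with one 0/1
  label (or NA) per line;
* PLINK text ``.ped``/``.map``.

No genotype quality control (call rate, HWE) is applied here: inputs are
assumed to be pre-cleaned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "minor", "major"]

_SPLIT_RE = re.compile(r"[,\s]+")


class GenotypeError(ValueError):
    """Raised for malformed genotype/phenotype input."""


def _chrom_sort_key(chrom: str):
    """Numeric-aware chromosome ordering: 1..22 before X, Y, MT."""
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with SNP metadata.

    Attributes
    ----------
    dosages:
        float64 array, shape (n_subjects, n_snps), entries in [0, 2] or NaN
        where missing.
    snp_meta:
        DataFrame with columns ``snp_id, chrom, pos, minor, major``;
        positions are 1-based and strictly increasing within a chromosome.
    subject_ids:
        length n_subjects array of string identifiers.
    missing_mask:
        optional boolean array marking entries that were (originally)
        missing; retained after imputation so imputed cells stay auditable.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D subjects x SNPs matrix")
        n, p = self.dosages.shape
        if self.subject_ids is None:
            self.subject_ids = np.array([f"ind{i}" for i in range(n)])
        self.subject_ids = np.asarray(self.subject_ids)
        if len(self.subject_ids) != n:
            raise GenotypeError(
                f"{len(self.subject_ids)} subject ids for {n} dosage rows"
            )
        if list(self.snp_meta.columns[:5]) != SNP_META_COLUMNS:
            raise GenotypeError(f"snp_meta must have columns {SNP_META_COLUMNS}")
        if len(self.snp_meta) != p:
            raise GenotypeError(
                f"{len(self.snp_meta)} metadata rows for {p} dosage columns"
            )
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"dosage {self.dosages[i, j]} outside [0, 2] at subject row "
                f"{i}, SNP {self.snp_meta['snp_id'].iloc[j]!r}"
            )
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.dosages.shape:
                raise GenotypeError("missing_mask shape mismatch")
        nan = np.isnan(self.dosages)
        if nan.any():
            # any NaN must be flagged as missing
            if self.missing_mask is None:
                self.missing_mask = nan
            elif not self.missing_mask[nan].all():
                raise GenotypeError("NaN dosage not flagged in missing_mask")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_freq(self) -> np.ndarray:
        """Per-SNP allele frequency of the dosage-counted allele."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_variance(self, ddof: int = 1) -> np.ndarray:
        """Per-SNP sample variance s_j^2 (requires no missing entries)."""
        if self.has_missing:
            raise GenotypeError(
                "snp_variance requires imputed data; call impute_missing_mean first"
            )
        return np.var(self.dosages, axis=0, ddof=ddof)

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            subject_ids=self.subject_ids.copy(),
            missing_mask=None if self.missing_mask is None else self.missing_mask[:, idx].copy(),
        )

    def take_subjects(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx].copy(),
            snp_meta=self.snp_meta.copy(),
            subject_ids=self.subject_ids[idx].copy(),
            missing_mask=None if self.missing_mask is None else self.missing_mask[idx].copy(),
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a GenotypeMatrix's subjects."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise GenotypeError("phenotype labels must be 1-D")
        vals = set(np.unique(self.labels).tolist())
        if not vals <= {0, 1}:
            raise GenotypeError(f"phenotype labels must be 0/1, got {sorted(vals)}")
        if len(vals) < 2:
            raise GenotypeError("phenotype must contain at least one case and one control")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def take(self, idx) -> "PhenotypeVector":
        return PhenotypeVector(self.labels[np.asarray(idx, dtype=int)])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def orient_minor_allele(G: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns whose counted-allele frequency exceeds 0.5.

    Flipped columns are transformed x -> 2 - x and their minor/major allele
    labels swapped.  A frequency of exactly 0.5 keeps the input orientation,
    which makes the operation idempotent.
    """
    freq = G.allele_freq()
    flip = freq > 0.5
    dos = G.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    meta = G.snp_meta.copy()
    if flip.any():
        minor = meta["minor"].to_numpy().copy()
        major = meta["major"].to_numpy().copy()
        minor[flip], major[flip] = major[flip], minor[flip].copy()
        meta["minor"] = minor
        meta["major"] = major
    return GenotypeMatrix(
        dosages=dos,
        snp_meta=meta,
        subject_ids=G.subject_ids.copy(),
        missing_mask=None if G.missing_mask is None else G.missing_mask.copy(),
    )


def impute_missing_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by the observed mean of its SNP column."""
    dos = G.dosages.copy()
    nan = np.isnan(dos)
    if not nan.any():
        return replace(G, dosages=dos)
    fully = nan.all(axis=0)
    if fully.any():
        j = int(np.argmax(fully))
        raise GenotypeError(
            f"SNP {G.snp_meta['snp_id'].iloc[j]!r} has no observed genotypes; "
            "cannot mean-impute"
        )
    col_mean = np.nanmean(dos, axis=0)
    jj = np.where(nan)
    dos[jj] = col_mean[jj[1]]
    mask = nan if G.missing_mask is None else (G.missing_mask | nan)
    return GenotypeMatrix(
        dosages=dos,
        snp_meta=G.snp_meta.copy(),
        subject_ids=G.subject_ids.copy(),
        missing_mask=mask,
    )


def _sort_genome_order(meta: pd.DataFrame) -> np.ndarray:
    chrom_rank = {
        c: i
        for i, c in enumerate(sorted(set(meta["chrom"]), key=_chrom_sort_key))
    }
    ckey = meta["chrom"].map(chrom_rank).to_numpy()
    return np.lexsort((meta["pos"].to_numpy(), ckey))


# ---------------------------------------------------------------------------
# mean-genotype ("BIMBAM") dialect
# ---------------------------------------------------------------------------

def read_mean_genotype(
    genotype_path: str | Path,
    position_path: str | Path,
    phenotype_path: str | Path,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a mean-genotype file triplet.

    Genotype rows are SNPs: ``snp_id, minor_allele, major_allele,
    dosage_1 ... dosage_n`` (comma and/or whitespace separated, ``NA`` for
    missing).  Position rows are ``snp_id, bp, chrom``.  The phenotype file
    holds one 0/1 label per line; ``NA`` drops the subject (logged).
    Columns are returned in genome order (chromosome, position).
    """
    snp_ids: list[str] = []
    minors: list[str] = []
    majors: list[str] = []
    rows: list[np.ndarray] = []
    with open(genotype_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [t for t in _SPLIT_RE.split(line) if t]
            if len(parts) < 4:
                raise GenotypeError(
                    f"{genotype_path}: row {ln} has fewer than 4 fields"
                )
            snp_ids.append(parts[0])
            minors.append(parts[1])
            majors.append(parts[2])
            vals = np.empty(len(parts) - 3)
            for k, tok in enumerate(parts[3:]):
                if tok.upper() == "NA":
                    vals[k] = np.nan
                else:
                    try:
                        vals[k] = float(tok)
                    except ValueError as exc:
                        raise GenotypeError(
                            f"{genotype_path}: row {ln}: bad dosage {tok!r}"
                        ) from exc
                    if not 0.0 <= vals[k] <= 2.0:
                        raise GenotypeError(
                            f"{genotype_path}: row {ln} (SNP {parts[0]!r}): "
                            f"dosage {tok} outside [0, 2]"
                        )
            rows.append(vals)
    if not rows:
        raise GenotypeError(f"{genotype_path}: empty genotype file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GenotypeError(
            f"{genotype_path}: inconsistent subject counts per row: {sorted(lengths)}"
        )

    posdf = pd.read_csv(
        position_path, sep=r"[,\s]+", engine="python", header=None,
        names=["snp_id", "pos", "chrom"], dtype={"snp_id": str, "chrom": str},
    )
    pos_map = posdf.set_index("snp_id")
    missing_ids = [s for s in snp_ids if s not in pos_map.index]
    if missing_ids:
        raise GenotypeError(
            f"{position_path}: no position for SNP(s) {missing_ids[:5]}"
        )
    unknown = set(pos_map.index) - set(snp_ids)
    if unknown:
        raise GenotypeError(
            f"{position_path}: unknown snp_id(s) not in genotype file: "
            f"{sorted(unknown)[:5]}"
        )

    labels: list[float] = []
    with open(phenotype_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok.upper() == "NA":
                labels.append(np.nan)
            elif tok in {"0", "1"}:
                labels.append(int(tok))
            else:
                raise GenotypeError(
                    f"{phenotype_path}: line {ln}: phenotype must be 0, 1 or NA"
                )
    n_subj = lengths.pop()
    if len(labels) != n_subj:
        raise GenotypeError(
            f"{phenotype_path}: {len(labels)} phenotypes for {n_subj} genotype "
            "columns"
        )
    labels_arr = np.asarray(labels, dtype=float)
    keep = ~np.isnan(labels_arr)
    if not keep.all():
        logger.warning(
            "dropping %d subject(s) with missing phenotype", int((~keep).sum())
        )

    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": pos_map.loc[snp_ids, "chrom"].astype(str).to_numpy(),
            "pos": pos_map.loc[snp_ids, "pos"].astype(int).to_numpy(),
            "minor": minors,
            "major": majors,
        }
    )
    dos = np.vstack(rows).T  # subjects x SNPs
    order = _sort_genome_order(meta)
    G = GenotypeMatrix(
        dosages=dos[keep][:, order],
        snp_meta=meta.iloc[order].reset_index(drop=True),
        subject_ids=np.array([f"ind{i}" for i in np.where(keep)[0]]),
    )
    y = PhenotypeVector(labels_arr[keep].astype(np.int8))
    return G, y


def write_mean_genotype(
    G: GenotypeMatrix,
    genotype_path: str | Path,
    position_path: str | Path,
    phenotype_path: str | Path | None = None,
    y: PhenotypeVector | None = None,
) -> None:
    """Write the mean-genotype triplet for ``G`` (and optionally ``y``)."""
    meta = G.snp_meta
    with open(genotype_path, "w") as fh:
        for j in range(G.n_snps):
            vals = G.dosages[:, j]
            toks = ["NA" if np.isnan(v) else format(v, "g") for v in vals]
            fh.write(
                f"{meta['snp_id'].iloc[j]}, {meta['minor'].iloc[j]}, "
                f"{meta['major'].iloc[j]}, " + ", ".join(toks) + "\n"
            )
    with open(position_path, "w") as fh:
        for j in range(G.n_snps):
            fh.write(
                f"{meta['snp_id'].iloc[j]}, {int(meta['pos'].iloc[j])}, "
                f"{meta['chrom'].iloc[j]}\n"
            )
    if phenotype_path is not None:
        if y is None:
            raise GenotypeError("phenotype_path given without a phenotype vector")
        with open(phenotype_path, "w") as fh:
            for v in y.labels:
                fh.write(f"{int(v)}\n")


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read PLINK text ``.ped``/``.map`` into minor-allele dosages.

    PLINK phenotype coding 1 (control) / 2 (case) maps to 0/1; 0 or -9
    drops the subject.  Allele "0" marks a missing call; a genotype with
    any missing allele becomes a missing dosage.  Triallelic SNPs are
    rejected.
    """
    mapdf = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    p = len(mapdf)
    subject_ids: list[str] = []
    phen: list[float] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise GenotypeError(
                    f"{ped_path}: row {ln}: expected {6 + 2 * p} fields "
                    f"(6 + 2x{p} alleles), got {len(parts)}"
                )
            subject_ids.append(f"{parts[0]}_{parts[1]}")
            code = parts[5]
            phen.append({"1": 0.0, "2": 1.0}.get(code, np.nan))
            allele_rows.append(parts[6:])

    n = len(allele_rows)
    if n == 0:
        raise GenotypeError(f"{ped_path}: empty pedigree file")
    dos = np.full((n, p), np.nan)
    minors: list[str] = []
    majors: list[str] = []
    alleles = np.array(allele_rows)  # n x 2p
    for j in range(p):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        observed = np.concatenate([a1, a2])
        observed = observed[observed != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise GenotypeError(
                f"{map_path}: SNP {mapdf['snp_id'].iloc[j]!r} has "
                f"{len(uniq)} alleles: {uniq.tolist()}"
            )
        if len(uniq) == 0:
            raise GenotypeError(
                f"{ped_path}: SNP {mapdf['snp_id'].iloc[j]!r} has no called genotypes"
            )
        ok = (a1 != "0") & (a2 != "0")
        if len(uniq) == 1:
            # monomorphic: observed allele is the major one, no minor copies
            minors.append(".")
            majors.append(str(uniq[0]))
            dos[ok, j] = 0.0
            continue
        # minor = least frequent (ties keep lexical order for determinism)
        order = np.lexsort((uniq, counts))
        minor = uniq[order[0]]
        major = uniq[order[-1]]
        minors.append(str(minor))
        majors.append(str(major))
        dos[ok, j] = (a1[ok] == minor).astype(float) + (a2[ok] == minor).astype(float)

    phen_arr = np.asarray(phen)
    keep = ~np.isnan(phen_arr)
    if not keep.all():
        logger.warning(
            "dropping %d subject(s) with missing PLINK phenotype", int((~keep).sum())
        )
    meta = pd.DataFrame(
        {
            "snp_id": mapdf["snp_id"].to_numpy(),
            "chrom": mapdf["chrom"].astype(str).to_numpy(),
            "pos": mapdf["pos"].astype(int).to_numpy(),
            "minor": minors,
            "major": majors,
        }
    )
    order = _sort_genome_order(meta)
    G = GenotypeMatrix(
        dosages=dos[keep][:, order],
        snp_meta=meta.iloc[order].reset_index(drop=True),
        subject_ids=np.asarray(subject_ids)[keep],
    )
    y = PhenotypeVector(phen_arr[keep].astype(np.int8))
    return G, y
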