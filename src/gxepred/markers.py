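"""Marker QC, imputation, and the realized (genomic) relationship matrix.

Markers are diploid-coded allele dosages in [0, 2] (tetraploid switchgrass has
disomic inheritance, so a biallelic SNP in a tetraploid still segregates as two
independent diploid loci and the ALT-allele count per individual is 0/1/2).
The kinship estimator is VanRaden's centered crossproduct,

    G = W W' / (2 * sum_m p_m (1 - p_m)),   W = dosages - 2 p,

with observed allele frequencies p, no shrinkage and no internal MAF floor
(QC is a separate, explicit step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strings parsed as a missing dosage in delimited text input
MISSING_SENTINELS = ("", "NA", ".", "nan", "NaN")


class MarkerQCError(ValueError):
    """Raised when marker QC or GRM construction cannot proceed."""


@dataclass
class DosageMatrix:
    """Individuals x markers allele-dosage matrix, missing entries as NaN."""

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("identifier lists do not match matrix dimensions")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker ALT allele frequency from non-missing calls (NaN if
        a marker has no calls at all)."""
        n_obs = (~np.isnan(self.dosages)).sum(axis=0)
        sums = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, sums / (2.0 * n_obs), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)


@dataclass
class RelationshipMatrix:
    """Symmetric PSD genomic kinship among individuals."""

    individual_ids: list[str]
    values: np.ndarray
    #: diagonal adjustment applied by PSD bending (0.0 if none was needed)
    bend: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("G shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("G is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        idx = pd.Index(self.individual_ids).get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"individuals absent from G: {missing[:5]}")
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  bend=self.bend, meta=dict(self.meta))


def filter_markers(dosage: DosageMatrix, max_missing_frac: float = 0.20,
                   min_maf: float = 0.005) -> DosageMatrix:
    """Retain markers with missing fraction < ``max_missing_frac`` and
    minor allele frequency > ``min_maf`` (both comparisons strict).

    A fully missing marker has no defined MAF and is removed by the
    missingness rule.
    """
    if dosage.n_markers == 0:
        raise MarkerQCError("empty dosage matrix")
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    miss = dosage.missing_fraction()
    maf = dosage.minor_allele_frequency()
    keep = (miss < max_missing_frac) & (np.nan_to_num(maf, nan=-1.0) > min_maf)
    if not keep.any():
        raise MarkerQCError("no markers survive QC")
    kept_ids = [m for m, k in zip(dosage.marker_ids, keep) if k]
    logger.info("marker QC: kept %d of %d markers", keep.sum(), keep.size)
    return DosageMatrix(list(dosage.individual_ids), kept_ids,
                        dosage.dosages[:, keep])


def impute_missing(dosage: DosageMatrix) -> DosageMatrix:
    """Fill missing dosages with the population mean of that marker."""
    x = dosage.dosages.copy()
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return DosageMatrix(list(dosage.individual_ids),
                            list(dosage.marker_ids), x)
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = dosage.marker_ids[int(np.argmax(all_missing))]
        raise MarkerQCError(f"marker {bad!r} has no non-missing calls")
    col_means = np.nanmean(x, axis=0)
    x[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    return DosageMatrix(list(dosage.individual_ids), list(dosage.marker_ids), x)


def realized_relationship(dosage: DosageMatrix,
                          psd_tol: float = 1e-8) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Requires a complete dosage matrix (run :func:`impute_missing` first).
    If the smallest eigenvalue is below ``-psd_tol`` the matrix is bent by
    adding ``|lambda_min| + 1e-6`` to the diagonal; the adjustment is recorded
    on the result.
    """
    x = dosage.dosages
    if np.isnan(x).any():
        raise MarkerQCError("dosage matrix has missing values; impute first")
    if dosage.n_individuals < 2:
        raise MarkerQCError("need at least 2 individuals")
    p = x.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise MarkerQCError("all markers monomorphic: zero denominator")
    w = x - 2.0 * p
    g = w @ w.T / denom
    g = (g + g.T) / 2.0
    bend = 0.0
    lam_min = float(np.linalg.eigvalsh(g)[0])
    if lam_min < -psd_tol:
        bend = abs(lam_min) + 1e-6
        g = g + bend * np.eye(g.shape[0])
        logger.warning("G bent by %.3g to restore PSD", bend)
    return RelationshipMatrix(list(dosage.individual_ids), g, bend=bend,
                              meta={"n_markers": dosage.n_markers,
                                    "denominator": denom})


# ---------------------------------------------------------------------------
# I/O


def read_dosage_tsv(path, sep: str = "\t") -> DosageMatrix:
    """Read a delimited dosage matrix: rows = individuals, header = marker
    IDs, first column = individual ID. Empty fields, 'NA' and '.' are missing.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    vals = df.replace(list(MISSING_SENTINELS), np.nan).astype(float).to_numpy()
    return DosageMatrix([str(i) for i in df.index],
                        [str(c) for c in df.columns], vals)


def write_dosage_tsv(dosage: DosageMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(dosage.dosages, index=dosage.individual_ids,
                      columns=dosage.marker_ids)
    df.to_csv(path, sep=sep, float_format="%.10g", na_rep="NA",
              index_label="individual_id")


def read_dosage_vcf(path) -> DosageMatrix:
    """Read dosages from a VCF: dosage = ALT allele count from the GT field.

    Only biallelic SNPs are used; other records are skipped with a logged
    count. Missing genotypes become NaN.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, marker_ids, skipped = [], [], 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref 1 het 2 unknown 3 hom-alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        rows.append(dos)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        marker_ids.append(mid)
    if skipped:
        logger.info("VCF: skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise MarkerQCError("no biallelic SNPs in VCF")
    return DosageMatrix(ids, marker_ids, np.column_stack(rows))


def write_grm_tsv(g: RelationshipMatrix, path, sep: str = "\t") -> None:
    """Square GRM with header row and ID column at full precision."""
    df = pd.DataFrame(g.values, index=g.individual_ids,
                      columns=g.individual_ids)
    df.to_csv(path, sep=sep, float_format="%.12g", index_label="individual_id")


def read_grm_tsv(path, sep: str = "\t") -> RelationshipMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return RelationshipMatrix([str(i) for i in df.index], df.to_numpy())
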