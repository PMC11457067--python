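"""Additive main effects and multiplicative interaction (AMMI) analysis.

AMMI decomposes a complete two-way table of genotype (or subpopulation) x
site means as

    Y_ij = mu + g_i + l_j + sum_k lambda_k alpha_ik gamma_jk + E_ij,

where mu is the grand mean, g_i and l_j are centered marginal effects, and
the multiplicative terms are the SVD of the double-centered interaction
matrix Z = Y - mu - g - l. The fraction of GxE captured by component k is
lambda_k^2 / sum lambda^2 (denominator = interaction sum of squares only).

Unbalanced designs are completed first by an additive-EM fill: missing cells
are iteratively replaced by mu + g_i + l_j re-estimated from the completed
table, leaving observed cells untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pheno import PhenotypeTable, aggregate_phenotypes

logger = logging.getLogger(__name__)


class AMMIError(ValueError):
    pass


@dataclass
class CellMeanMatrix:
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # may contain NaN before completion
    fill_mask: np.ndarray | None = None  # True where a cell was EM-filled

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("shape mismatch")
        if len(self.row_ids) < 2 or len(self.col_ids) < 2:
            raise AMMIError("need at least 2 rows and 2 columns")


@dataclass
class AMMIResult:
    grand_mean: float
    row_effects: pd.Series
    col_effects: pd.Series
    singular_values: np.ndarray          # descending, >= 0
    row_scores: np.ndarray               # rows x K, orthonormal columns
    col_scores: np.ndarray               # cols x K, orthonormal columns
    variance_fraction: np.ndarray        # lambda^2 / sum lambda^2, per kept k
    residuals: np.ndarray
    zero_interaction: bool = False
    near_degenerate: list[tuple[int, int]] = field(default_factory=list)

    def row_score_table(self) -> pd.DataFrame:
        k = self.row_scores.shape[1]
        df = pd.DataFrame(self.row_scores, index=self.row_effects.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "mean", self.grand_mean + self.row_effects.values)
        return df

    def col_score_table(self) -> pd.DataFrame:
        k = self.col_scores.shape[1]
        df = pd.DataFrame(self.col_scores, index=self.col_effects.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "mean", self.grand_mean + self.col_effects.values)
        return df

    def component_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, len(self.singular_values) + 1),
            "singular_value": self.singular_values,
            "variance_fraction": self.variance_fraction,
        })


def build_cell_means(table: PhenotypeTable, level: str = "individual",
                     drop_admixed: bool = False,
                     trait: str = "biomass") -> CellMeanMatrix:
    """Row x site mean matrix at the individual or subpopulation level."""
    if level not in ("individual", "subpopulation"):
        raise ValueError("level must be 'individual' or 'subpopulation'")
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    rec = table.records
    rec = rec[rec["trait"] == trait].copy()
    if drop_admixed:
        admixed = table.admixed_of()
        keep = ~rec["genotype_id"].map(admixed).fillna(False).astype(bool)
        rec = rec[keep]
    if level == "subpopulation":
        subpop = table.subpopulation_of()
        rec["row"] = rec["genotype_id"].map(subpop)
    else:
        rec["row"] = rec["genotype_id"]
    wide = rec.pivot_table(index="row", columns="site", values="value",
                           aggfunc="mean")
    wide = wide.dropna(axis=0, how="all").dropna(axis=1, how="all")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise AMMIError("fewer than 2 non-empty rows or columns")
    return CellMeanMatrix([str(r) for r in wide.index],
                          [str(c) for c in wide.columns], wide.to_numpy())


def _additive_fit(y: np.ndarray):
    mu = y.mean()
    g = y.mean(axis=1) - mu
    l = y.mean(axis=0) - mu
    return mu, g, l


def complete_matrix(m: CellMeanMatrix, tol: float = 1e-12,
                    max_iter: int = 1000) -> CellMeanMatrix:
    """EM completion under the additive model mu + g_i + l_j.

    Observed cells are never modified. The per-iteration sum of squared fill
    changes is non-increasing and iteration stops at ``tol``.
    """
    y = m.values.copy()
    miss = np.isnan(y)
    if not miss.any():
        return CellMeanMatrix(list(m.row_ids), list(m.col_ids), y,
                              fill_mask=np.zeros_like(miss))
    if miss.all(axis=1).any() or miss.all(axis=0).any():
        raise AMMIError("a row or column has no observed cells")
    # start from row/column means of observed cells
    row_means = np.nanmean(y, axis=1)
    y[miss] = np.broadcast_to(row_means[:, None], y.shape)[miss]
    for _ in range(max_iter):
        mu, g, l = _additive_fit(y)
        fill = mu + g[:, None] + l[None, :]
        delta = float(np.sum((y[miss] - fill[miss]) ** 2))
        y[miss] = fill[miss]
        if delta < tol:
            break
    frac = miss.mean()
    logger.info("EM fill: %.1f%% of cells imputed", 100 * frac)
    return CellMeanMatrix(list(m.row_ids), list(m.col_ids), y, fill_mask=miss)


def fit_ammi(m: CellMeanMatrix, n_components: int | None = None,
             zero_tol: float = 1e-12) -> AMMIResult:
    """Fit the AMMI decomposition to a complete cell-mean matrix.

    ``n_components`` defaults to min(rows, cols) - 1 (the full interaction
    rank). Sign convention: each component is flipped so that the site score
    of largest magnitude is positive, making biplots reproducible.
    """
    y = m.values
    if np.isnan(y).any():
        raise AMMIError("matrix has missing cells; run complete_matrix first")
    nr, nc = y.shape
    kmax = min(nr, nc) - 1
    k = kmax if n_components is None else int(n_components)
    if not (1 <= k <= kmax):
        raise AMMIError(f"n_components must be in [1, {kmax}]")
    mu, g, l = _additive_fit(y)
    z = y - mu - g[:, None] - l[None, :]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :kmax], s[:kmax], vt[:kmax]
    # pin the SVD sign: largest-|.| site score positive per component
    for j in range(kmax):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    ss = s ** 2
    total = ss.sum()
    zero_interaction = total < zero_tol
    frac = np.zeros(kmax) if zero_interaction else ss / total
    near = [(a, a + 1) for a in range(kmax - 1)
            if s[a] > 0 and (s[a] - s[a + 1]) / s[a] < 1e-6]
    if near:
        logger.warning("near-degenerate singular value pairs: %s", near)
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    return AMMIResult(
        grand_mean=float(mu),
        row_effects=pd.Series(g, index=m.row_ids),
        col_effects=pd.Series(l, index=m.col_ids),
        singular_values=s,
        row_scores=u[:, :k],
        col_scores=vt[:k].T,
        variance_fraction=frac,
        residuals=z - recon,
        zero_interaction=zero_interaction,
        near_degenerate=near,
    )
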