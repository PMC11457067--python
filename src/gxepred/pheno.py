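"""Phenotype and site tables: ingestion, aggregation, surrogate site means.

Phenotypes live in long format — one record per (genotype, site, year, trait)
— with genotype metadata (subpopulation, admixed flag) alongside. Traits are
``biomass`` (square-root grams, dead plants recorded as 0), ``fall_height``
(cm) and ``flowering_time`` (ordinal day of year). Within-site clone
replicates are averaged into the genotype-site-year cell before year
averaging; year means are over the available years (a missing year drops out
of the mean, a recorded dead-plant zero stays in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("biomass", "fall_height", "flowering_time")
SUBPOPULATIONS = ("Gulf", "Midwest", "Coastal", "Texas")
#: default pair of sites whose genotype means define the yield-surrogate
#: columns (the two sites jointly covering nearly all individuals)
SURROGATE_SITES = ("KBSM", "CLMB")

PHENO_COLUMNS = ["genotype_id", "site", "year", "trait", "value"]
SITE_COLUMNS = ["site", "region", "latitude", "longitude", "elevation"]
META_COLUMNS = ["genotype_id", "subpopulation", "admixed"]


class PhenotypeError(ValueError):
    pass


def transform_biomass(raw_grams):
    """Square-root transform of grams dry biomass (0 for dead plants)."""
    arr = np.asarray(raw_grams, dtype=float)
    if np.any(arr < 0):
        raise PhenotypeError("negative biomass weight")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(raw_grams) or arr.ndim == 0 else out


@dataclass
class SiteTable:
    """Site metadata: code, region (South/Middle/North), lat/lon/elevation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SITE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def sites(self) -> list[str]:
        return list(self.data["site"])

    def latitude(self) -> pd.Series:
        return self.data.set_index("site")["latitude"]

    def region(self) -> pd.Series:
        return self.data.set_index("site")["region"]


@dataclass
class PhenotypeTable:
    """Long-format phenotype records plus per-genotype metadata."""

    records: pd.DataFrame
    metadata: pd.DataFrame = None  # genotype_id, subpopulation, admixed
    aggregated: bool = False

    def __post_init__(self) -> None:
        missing = set(PHENO_COLUMNS) - {"year"} - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        if self.metadata is None:
            gids = sorted(self.records["genotype_id"].unique())
            self.metadata = pd.DataFrame(
                {"genotype_id": gids, "subpopulation": "unknown",
                 "admixed": False})
        self.metadata = self.metadata.reset_index(drop=True)
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        rec = self.records
        ft = rec.loc[rec["trait"] == "flowering_time", "value"]
        if len(ft) and ((ft < 1) | (ft > 366)).any():
            raise PhenotypeError("flowering_time outside [1, 366]")
        for trait in ("fall_height", "biomass"):
            v = rec.loc[rec["trait"] == trait, "value"]
            if len(v) and (v < 0).any():
                raise PhenotypeError(f"negative {trait} value")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype_id"].unique())

    def subpopulation_of(self) -> pd.Series:
        return self.metadata.set_index("genotype_id")["subpopulation"]

    def admixed_of(self) -> pd.Series:
        return self.metadata.set_index("genotype_id")["admixed"].astype(bool)

    def sites_observed(self, trait: str = "biomass") -> pd.Series:
        """Number of distinct sites at which each genotype has ``trait``."""
        sub = self.records[self.records["trait"] == trait]
        return sub.groupby("genotype_id")["site"].nunique()


def aggregate_phenotypes(table: PhenotypeTable) -> PhenotypeTable:
    """Collapse to one record per (genotype, site, trait).

    Clone replicates are first averaged within (genotype, site, year, trait),
    then years are averaged (mean over available years). Idempotent: an
    already aggregated table passes through unchanged.
    """
    rec = table.records
    if "year" in rec.columns and rec["year"].notna().any():
        cell = (rec.groupby(["genotype_id", "site", "year", "trait"],
                            sort=True)["value"].mean().reset_index())
        agg = (cell.groupby(["genotype_id", "site", "trait"], sort=True)
               ["value"].mean().reset_index())
    else:
        agg = (rec.groupby(["genotype_id", "site", "trait"], sort=True)
               ["value"].mean().reset_index())
    return PhenotypeTable(agg, table.metadata.copy(), aggregated=True)


def surrogate_site_means(table: PhenotypeTable,
                         sites: tuple[str, ...] = SURROGATE_SITES,
                         trait: str = "flowering_time") -> pd.Series:
    """Per-genotype mean of site-level ``trait`` values over ``sites``.

    A genotype present at only one of the listed sites keeps that single
    site's value; genotypes absent at all listed sites are omitted (logged).
    """
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    rec = table.records
    sub = rec[(rec["trait"] == trait) & (rec["site"].isin(list(sites)))]
    out = sub.groupby("genotype_id")["value"].mean()
    n_all = rec["genotype_id"].nunique()
    if len(out) < n_all:
        logger.info("surrogate %s at %s: %d of %d genotypes covered",
                    trait, sites, len(out), n_all)
    return out
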