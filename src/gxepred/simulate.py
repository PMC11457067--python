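"""Synthetic genotypes and multi-site, multitrait phenotypes.

The generator emulates the statistical structure of a wild-collected
perennial-grass diversity panel evaluated as spaced plants across a
latitudinal transect of common gardens:

* four structured subpopulations of genotypes under a Balding-Nichols model
  (beta-distributed subpopulation allele frequencies around an ancestral
  frequency, divergence F);
* ten sites in three latitude-ordered regions (South/Middle/North);
* genotype-by-environment interaction dominated by a north-south axis:
  between-site genetic correlations decay exponentially with the latitude
  gap, and subpopulation biomass values get a latitude-aligned contrast
  (northern-adapted groups overperform north, southern groups south);
* three traits — biomass (sqrt-gram scale, zeros for dead plants), fall
  height (cm, no GxE) and flowering time (day of year, no GxE) — with target
  genetic correlations to overall biomass of 0.85 (height) and 0.45
  (flowering), and 0.31 between the surrogates;
* unbalanced replication: 53% of genotypes at 8-10 sites, 36% at <= 5 sites,
  the rest at 6-7; three years of records per genotype-site cell.

Breeding values are drawn as vec(g) ~ MVN(0, Ta (x) G) where G is computed
from the simulated markers and Ta is assembled from the site-correlation
matrix and the surrogate correlations via a latent-factor construction that
is positive semidefinite by design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .markers import DosageMatrix, RelationshipMatrix, impute_missing, \
    realized_relationship
from .pheno import PhenotypeTable, SiteTable

logger = logging.getLogger(__name__)

#: the ten-garden latitudinal transect the generator emulates
DEFAULT_SITES = pd.DataFrame(
    [
        ("KING", "South", 27.5498, -97.8810, 22),
        ("PKLE", "South", 30.3839, -97.7293, 235),
        ("TMPL", "South", 31.0433, -97.3494, 182),
        ("OVTN", "South", 32.3029, -94.9794, 138),
        ("STIL", "Middle", 35.9911, -97.0464, 280),
        ("CLMB", "Middle", 38.8969, -92.2178, 268),
        ("LINC", "North", 41.1543, -96.4153, 348),
        ("FRMI", "North", 41.8367, -88.2396, 225),
        ("KBSM", "Middle", 42.4196, -85.3712, 289),
        ("BRKG", "North", 44.3068, -96.6705, 503),
    ],
    columns=["site", "region", "latitude", "longitude", "elevation"],
)

#: subpopulations adapted to northern climates (positive latitude contrast)
NORTHERN_SUBPOPS = ("Midwest", "Coastal")

YEARS = (2019, 2020, 2021)


@dataclass
class SimulationConfig:
    n_per_subpop: dict = field(default_factory=lambda: {
        "Texas": 119, "Coastal": 147, "Midwest": 67, "Gulf": 51})
    n_markers: int = 2000
    fst: float = 0.15
    missing_marker_rate: float = 0.0
    sites: pd.DataFrame = field(default_factory=lambda: DEFAULT_SITES.copy())
    gxe_decay: float = 0.12           # per degree latitude
    h2: dict = field(default_factory=lambda: {
        "biomass": 0.6, "fall_height": 0.7, "flowering_time": 0.8})
    rg_height_biomass: float = 0.85
    rg_flowering_biomass: float = 0.45
    rg_flowering_height: float = 0.31
    sigma_g: dict = field(default_factory=lambda: {
        "biomass": 4.0, "fall_height": 25.0, "flowering_time": 12.0})
    year_sd: dict = field(default_factory=lambda: {
        "biomass": 1.5, "fall_height": 8.0, "flowering_time": 5.0})
    frac_8_10_sites: float = 0.53
    frac_le5_sites: float = 0.36
    subpop_contrast: float = 2.5      # sqrt-g biomass, latitude-aligned GxE
    dead_bv_threshold: float = -6.0   # total site value below this may die
    dead_prob: float = 0.5
    admixed_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        t3 = self.trait_corr()
        if np.linalg.eigvalsh(t3)[0] < -1e-10:
            raise ValueError("trait correlation targets are not PSD")
        for fr in (self.frac_8_10_sites, self.frac_le5_sites):
            if not 0 <= fr <= 1:
                raise ValueError("replication fractions must be in [0, 1]")
        if self.frac_8_10_sites + self.frac_le5_sites > 1:
            raise ValueError("replication fractions exceed 1")

    def trait_corr(self) -> np.ndarray:
        r = np.eye(3)
        r[0, 1] = r[1, 0] = self.rg_height_biomass
        r[0, 2] = r[2, 0] = self.rg_flowering_biomass
        r[1, 2] = r[2, 1] = self.rg_flowering_height
        return r


@dataclass
class SimulationTruth:
    genotype_ids: list
    site_codes: list
    subpopulation: dict
    bv_biomass: np.ndarray        # n x n_sites, incl. subpop contrast
    bv_height: np.ndarray         # n
    bv_flowering: np.ndarray      # n
    bv_biomass_overall: np.ndarray  # n, the latent overall-merit factor
    Ta: np.ndarray                # (n_sites + 2) column genetic covariance
    site_corr: np.ndarray         # n_sites x n_sites
    column_labels: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "genotype_ids": list(self.genotype_ids),
            "site_codes": list(self.site_codes),
            "subpopulation": dict(self.subpopulation),
            "bv_biomass": self.bv_biomass.tolist(),
            "bv_height": self.bv_height.tolist(),
            "bv_flowering": self.bv_flowering.tolist(),
            "bv_biomass_overall": self.bv_biomass_overall.tolist(),
            "Ta": self.Ta.tolist(),
            "site_corr": self.site_corr.tolist(),
            "column_labels": list(self.column_labels),
        }
        return json.dumps(payload)


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None):
    """Balding-Nichols structured genotypes.

    Ancestral frequencies ~ U(0.05, 0.95); per-subpopulation frequencies
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F); dosages ~ Binomial(2, p_subpop).
    Returns (DosageMatrix, metadata DataFrame with subpopulation + admixed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_markers
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.fst
    rows, gids, subpops = [], [], []
    for sp, n_sp in config.n_per_subpop.items():
        if f > 0:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_sp = rng.beta(a, b)
        else:
            p_sp = p_anc
        dos = rng.binomial(2, p_sp, size=(n_sp, m)).astype(float)
        rows.append(dos)
        gids.extend(f"{sp[:2].upper()}{i:04d}" for i in range(n_sp))
        subpops.extend([sp] * n_sp)
    x = np.vstack(rows)
    if config.missing_marker_rate > 0:
        miss = rng.random(x.shape) < config.missing_marker_rate
        x[miss] = np.nan
    n = x.shape[0]
    admixed = np.zeros(n, dtype=bool)
    n_adm = int(round(config.admixed_frac * n))
    if n_adm:
        admixed[rng.choice(n, size=n_adm, replace=False)] = True
    meta = pd.DataFrame({"genotype_id": gids, "subpopulation": subpops,
                         "admixed": admixed})
    markers = [f"M{j:05d}" for j in range(m)]
    return DosageMatrix(gids, markers, x), meta


def _assemble_column_covariance(config: SimulationConfig):
    """Covariance of (biomass at each site, height, flowering) BVs.

    Built from the latent model: site biomass x ~ N(0, C) with
    C_ab = exp(-decay |lat_a - lat_b|); overall merit m = 1'x / sqrt(1'C1);
    height = r_h m + orthogonal noise; flowering correlated with both m and
    height's orthogonal part so the surrogate-surrogate correlation hits its
    target. PSD by construction.
    """
    lat = config.sites["latitude"].to_numpy()
    c = np.exp(-config.gxe_decay * np.abs(lat[:, None] - lat[None, :]))
    sb = config.sigma_g["biomass"]
    sh = config.sigma_g["fall_height"]
    sf = config.sigma_g["flowering_time"]
    r_h, r_f, r_hf = (config.rg_height_biomass, config.rg_flowering_biomass,
                      config.rg_flowering_height)
    w = c @ np.ones(len(lat))
    denom = np.sqrt(w.sum())
    ns = len(lat)
    t = ns + 2
    ta = np.zeros((t, t))
    ta[:ns, :ns] = sb ** 2 * c
    ta[:ns, ns] = ta[ns, :ns] = sb * sh * r_h * w / denom
    ta[:ns, ns + 1] = ta[ns + 1, :ns] = sb * sf * r_f * w / denom
    ta[ns, ns] = sh ** 2
    ta[ns + 1, ns + 1] = sf ** 2
    ta[ns, ns + 1] = ta[ns + 1, ns] = sh * sf * r_hf
    return ta, c


def simulate_phenotypes(dosage: DosageMatrix, config: SimulationConfig,
                        metadata: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        G: RelationshipMatrix | None = None):
    """Draw breeding values under Ta (x) G and emit a long phenotype table.

    Returns (PhenotypeTable with per-year records, SimulationTruth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if np.isnan(dosage.dosages).any():
        dosage = impute_missing(dosage)
    if G is None:
        G = realized_relationship(dosage)
    sites = SiteTable(config.sites)
    site_codes = sites.sites
    lat = config.sites["latitude"].to_numpy()
    ns = len(site_codes)
    gids = list(dosage.individual_ids)
    n = len(gids)
    subpop = metadata.set_index("genotype_id")["subpopulation"]

    ta, c = _assemble_column_covariance(config)

    # latent-factor draw (guarantees cov = Ta (x) G):
    # x = L_G Z L_C'  ->  site biomass factors;  m = overall merit factor
    eigval, eigvec = np.linalg.eigh(G.values)
    lg = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))
    cc = np.linalg.cholesky(c + 1e-10 * np.eye(ns))
    x = lg @ rng.standard_normal((n, ns)) @ cc.T
    w = c @ np.ones(ns)
    denom = np.sqrt(w.sum())
    m_fac = x @ np.ones(ns) / denom
    eta_h = lg @ rng.standard_normal(n)
    eta_f = lg @ rng.standard_normal(n)
    r_h, r_f, r_hf = (config.rg_height_biomass, config.rg_flowering_biomass,
                      config.rg_flowering_height)
    beta = (r_hf - r_h * r_f) / np.sqrt(1 - r_h ** 2)
    gamma = np.sqrt(1 - r_f ** 2 - beta ** 2)
    sb = config.sigma_g["biomass"]
    sh = config.sigma_g["fall_height"]
    sf = config.sigma_g["flowering_time"]
    bv_b = sb * x
    bv_h = sh * (r_h * m_fac + np.sqrt(1 - r_h ** 2) * eta_h)
    bv_f = sf * (r_f * m_fac + beta * eta_h + gamma * eta_f)

    # latitude-aligned subpopulation contrast (deterministic GxE component)
    lat_sd = lat.std()
    lat_z = (lat - lat.mean()) / lat_sd if lat_sd > 0 else np.zeros_like(lat)
    direction = np.where(pd.Series(gids).map(subpop).isin(NORTHERN_SUBPOPS),
                         1.0, -1.0).astype(float)
    contrast = config.subpop_contrast * np.outer(direction, lat_z)
    bv_b_total = bv_b + contrast

    # site means: biomass declines with latitude on the sqrt-g scale;
    # flowering is later at higher latitude; height roughly flat
    site_mean_b = 24.0 - 0.35 * (lat - lat.min())
    site_mean_h = np.full(ns, 160.0)
    site_mean_f = 150.0 + 2.0 * (lat - lat.min())

    # residual sd per trait so that the 3-year mean hits the target h2
    resid_sd, year_sd = {}, dict(config.year_sd)
    for trait in ("biomass", "fall_height", "flowering_time"):
        sg2 = config.sigma_g[trait] ** 2
        h2 = config.h2[trait]
        err_needed = sg2 * (1 - h2) / h2
        cell_var = max(err_needed - year_sd[trait] ** 2 / 3.0, 0.0)
        resid_sd[trait] = np.sqrt(cell_var)

    # replication profile
    u = rng.random(n)
    n_sites_per_geno = np.empty(n, dtype=int)
    hi = u < config.frac_8_10_sites
    lo = (~hi) & (u < config.frac_8_10_sites + config.frac_le5_sites)
    mid = ~(hi | lo)
    n_sites_per_geno[hi] = rng.integers(8, 11, size=hi.sum())
    n_sites_per_geno[lo] = rng.integers(2, 6, size=lo.sum())
    n_sites_per_geno[mid] = rng.integers(6, 8, size=mid.sum())
    n_sites_per_geno = np.minimum(n_sites_per_geno, ns)

    records = []
    dead_draw = rng.random((n, ns))
    for gi, gid in enumerate(gids):
        chosen = rng.choice(ns, size=n_sites_per_geno[gi], replace=False)
        for si in chosen:
            cell_noise = {
                "biomass": rng.normal(0, resid_sd["biomass"]),
                "fall_height": rng.normal(0, resid_sd["fall_height"]),
                "flowering_time": rng.normal(0, resid_sd["flowering_time"]),
            }
            dead = (bv_b_total[gi, si] < config.dead_bv_threshold
                    and dead_draw[gi, si] < config.dead_prob)
            cell_b = site_mean_b[si] + bv_b_total[gi, si] + cell_noise["biomass"]
            cell_h = site_mean_h[si] + bv_h[gi] + cell_noise["fall_height"]
            cell_f = site_mean_f[si] + bv_f[gi] + cell_noise["flowering_time"]
            for yr in YEARS:
                vb = 0.0 if dead else max(
                    cell_b + rng.normal(0, year_sd["biomass"]), 0.0)
                vh = max(cell_h + rng.normal(0, year_sd["fall_height"]), 0.0)
                vf = float(np.clip(
                    cell_f + rng.normal(0, year_sd["flowering_time"]), 1, 366))
                site = site_codes[si]
                records.append((gid, site, yr, "biomass", vb))
                records.append((gid, site, yr, "fall_height", vh))
                records.append((gid, site, yr, "flowering_time", vf))

    rec = pd.DataFrame(records, columns=["genotype_id", "site", "year",
                                         "trait", "value"])
    table = PhenotypeTable(rec, metadata.copy())
    truth = SimulationTruth(
        genotype_ids=gids, site_codes=site_codes,
        subpopulation={g: subpop[g] for g in gids},
        bv_biomass=bv_b_total, bv_height=bv_h, bv_flowering=bv_f,
        bv_biomass_overall=sb * m_fac, Ta=ta, site_corr=c,
        column_labels=site_codes + ["fall_height", "flowering_time"],
    )
    return table, truth


FIXTURE_SIZES = {
    "tiny": dict(n_per_subpop={"Texas": 10, "Coastal": 10, "Midwest": 10,
                               "Gulf": 10},
                 n_markers=200, site_subset=["KING", "CLMB", "KBSM", "BRKG"]),
    "small": dict(n_per_subpop={"Texas": 93, "Coastal": 115, "Midwest": 52,
                                "Gulf": 40},
                  n_markers=2000, site_subset=None),
    "panel": dict(n_per_subpop={"Texas": 119, "Coastal": 147,
                                    "Midwest": 67, "Gulf": 51},
                      n_markers=5000, site_subset=None),
}


def make_config(size: str = "small", seed: int = 0,
                **overrides) -> SimulationConfig:
    preset = FIXTURE_SIZES[size]
    sites = DEFAULT_SITES.copy()
    if preset["site_subset"]:
        sites = sites[sites["site"].isin(preset["site_subset"])].reset_index(
            drop=True)
    kwargs = dict(n_per_subpop=dict(preset["n_per_subpop"]),
                  n_markers=preset["n_markers"], sites=sites, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def simulate_dataset(config: SimulationConfig):
    """Genotypes + phenotypes + G in one call. Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    dosage, meta = simulate_genotypes(config, rng)
    complete = impute_missing(dosage) if np.isnan(dosage.dosages).any() \
        else dosage
    G = realized_relationship(complete)
    table, truth = simulate_phenotypes(complete, config, meta, rng, G=G)
    return dosage, meta, G, table, truth


def make_fixture(size: str, seed: int, out_dir) -> dict:
    """Write dosage/phenotype/site TSVs plus a truth JSON to ``out_dir``."""
    from .markers import write_dosage_tsv, write_grm_tsv

    config = make_config(size, seed)
    dosage, meta, G, table, truth = simulate_dataset(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosage": out / "dosage.tsv",
        "grm": out / "grm.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "metadata": out / "metadata.tsv",
        "sites": out / "sites.tsv",
        "truth": out / "truth.json",
    }
    write_dosage_tsv(dosage, paths["dosage"])
    write_grm_tsv(G, paths["grm"])
    gio.write_phenotypes(table, paths["phenotypes"], paths["metadata"])
    gio.write_sites(SiteTable(config.sites), paths["sites"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
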