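"""Delimited-text readers/writers and run configuration.

Formats (all TSV):
  phenotypes  genotype_id, site, year, trait, value
  sites       site, region, latitude, longitude, elevation
  metadata    genotype_id, subpopulation, admixed
Values round-trip at >= 10 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .pheno import (META_COLUMNS, PHENO_COLUMNS, SITE_COLUMNS, PhenotypeTable,
                    SiteTable)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


def read_phenotypes(pheno_path, metadata_path=None) -> PhenotypeTable:
    rec = pd.read_csv(pheno_path, sep="\t")
    missing = set(PHENO_COLUMNS) - {"year"} - set(rec.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns {sorted(missing)}")
    rec["genotype_id"] = rec["genotype_id"].astype(str)
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t")
        meta["genotype_id"] = meta["genotype_id"].astype(str)
        meta["admixed"] = meta["admixed"].astype(bool)
    aggregated = "year" not in rec.columns or rec["year"].isna().all()
    return PhenotypeTable(rec, meta, aggregated=aggregated)


def write_phenotypes(table: PhenotypeTable, pheno_path, metadata_path=None) -> None:
    cols = [c for c in PHENO_COLUMNS if c in table.records.columns]
    table.records[cols].to_csv(pheno_path, sep="\t", index=False,
                               float_format=FLOAT_FMT)
    if metadata_path is not None:
        table.metadata[META_COLUMNS].to_csv(metadata_path, sep="\t",
                                            index=False)


def read_sites(path) -> SiteTable:
    return SiteTable(pd.read_csv(path, sep="\t"))


def write_sites(sites: SiteTable, path) -> None:
    sites.data[SITE_COLUMNS].to_csv(path, sep="\t", index=False,
                                    float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG = {
    "qc": {"max_missing_frac": 0.20, "min_maf": 0.005},
    "gibbs": {"n_iter": 3000, "burn_in": 200, "thin": 5},
    "cv": {"folds": 8, "reps": 5, "min_sites": 6, "min_subpop": 60,
           "scenarios": ["CV1", "CV2_1site", "CV2_2site", "CV2_3site",
                         "CV2_4site", "CV2_5site"]},
    "surrogate_sites": ["KBSM", "CLMB"],
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    return cfg


def write_resolved_config(cfg: dict, out_dir, seed=None) -> Path:
    """Write the fully resolved config next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    payload = dict(cfg)
    payload["_provenance"] = {"package": "gxepred", "version": __version__,
                              "seed": seed}
    path = out_dir / "config.resolved.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def write_json_summary(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
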