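"""Sparse-testing cross-validation: eligibility, folds, masking, scoring.

Validation populations are built per subpopulation from genotypes with
biomass observed at more than five sites (reliable observed breeding values);
subpopulations with too few eligible genotypes are dropped. Eligible
genotypes are randomly split into k folds; one fold at a time is the
validation set whose training data are reduced according to a scenario:

  CV1        no phenotypic data at all (untested genotype)
  CV2_ksite  biomass kept at k randomly chosen observed sites (k = 1..5)
  FT         only the flowering-time surrogate column
  HT         only the fall-height surrogate column
  FT_HT      both surrogate columns
  B1         one biomass site (within the surrogate-augmented response)
  B1_FT      one biomass site plus flowering time
  B5         five biomass sites (surrogate-augmented response)

Training genotypes keep all their data. Predictive ability is the Pearson
correlation, per site, between predicted and observed genotype-site means
over validation genotypes whose training data excluded that site; scenario
summaries average over sites, then folds, then replicates. The observed
breeding value is the genotype-site mean phenotype (3-year mean).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import (ResponseMatrix, build_response, predict_masked,
                    run_gibbs)
from .markers import RelationshipMatrix
from .pheno import PhenotypeTable, aggregate_phenotypes

logger = logging.getLogger(__name__)

#: scenario -> (number of biomass sites kept, surrogate columns kept,
#:              response includes surrogate columns)
SCENARIOS = {
    "CV1": (0, (), False),
    "CV2_1site": (1, (), False),
    "CV2_2site": (2, (), False),
    "CV2_3site": (3, (), False),
    "CV2_4site": (4, (), False),
    "CV2_5site": (5, (), False),
    "FT": (0, ("flowering_time",), True),
    "HT": (0, ("fall_height",), True),
    "FT_HT": (0, ("flowering_time", "fall_height"), True),
    "B1": (1, (), True),
    "B1_FT": (1, ("flowering_time",), True),
    "B5": (5, (), True),
}


class CVError(ValueError):
    pass


def eligible_validation_set(table: PhenotypeTable, min_sites: int = 6,
                            min_subpop: int = 60) -> dict[str, list[str]]:
    """Eligible validation genotypes per subpopulation.

    Genotypes need biomass at >= ``min_sites`` sites and must not be admixed
    (admixed individuals stay in training data but are never validated).
    Subpopulations with fewer than ``min_subpop`` eligible genotypes are
    dropped with a warning.
    """
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    counts = table.sites_observed("biomass")
    admixed = table.admixed_of()
    subpop = table.subpopulation_of()
    eligible = counts[counts >= min_sites].index
    eligible = [g for g in eligible if not bool(admixed.get(g, False))]
    out: dict[str, list[str]] = {}
    for sp, members in pd.Series(eligible).groupby(
            pd.Series(eligible).map(subpop)):
        members = sorted(members)
        if len(members) < min_subpop:
            logger.warning("subpopulation %s dropped: %d eligible < %d",
                           sp, len(members), min_subpop)
            continue
        out[str(sp)] = members
    return out


def assign_folds(genotypes: list[str], k: int = 8, seed: int = 0) -> dict[str, int]:
    """Random folds 1..k of sizes differing by at most one (seeded).

    The genotype list is sorted before shuffling, so the assignment depends
    only on the set of IDs and the seed, not on input order.
    """
    genotypes = sorted(genotypes)
    if len(genotypes) < k:
        raise CVError(f"{len(genotypes)} genotypes < {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genotypes))
    folds = np.arange(len(genotypes)) % k + 1
    return {genotypes[i]: int(folds[j]) for j, i in enumerate(perm)}


@dataclass
class CVScheme:
    """One (scenario, subpopulation, replicate, fold) training configuration."""

    scenario: str
    subpopulation: str
    replicate: int
    fold: int
    validation: list[str]
    mask: np.ndarray                    # True = cell hidden from training
    response: ResponseMatrix
    #: cells to score: (genotype row, site column) pairs
    score_cells: list[tuple[int, int]] = field(default_factory=list)


def build_training_mask(response: ResponseMatrix, validation: list[str],
                        scenario: str, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of response cells hidden from training for one fold.

    Validation genotypes keep only what the scenario allows; training
    genotypes keep everything. For CV2-style scenarios the kept biomass sites
    are sampled uniformly without replacement from the genotype's observed
    sites; a genotype observed at fewer sites than requested keeps them all
    (logged).
    """
    if scenario not in SCENARIOS:
        raise CVError(f"unknown scenario {scenario!r}")
    keep_k, keep_surrogates, _ = SCENARIOS[scenario]
    obs = response.observed_mask()
    mask = np.zeros_like(obs)
    site_cols = [i for i, c in enumerate(response.column_labels)
                 if c in response.site_columns]
    sur_cols = {c: i for i, c in enumerate(response.column_labels)
                if c not in response.site_columns}
    row_of = {g: i for i, g in enumerate(response.genotype_ids)}
    for g in validation:
        j = row_of[g]
        observed_sites = [i for i in site_cols if obs[j, i]]
        if keep_k >= len(observed_sites):
            kept = list(observed_sites)
            if keep_k > len(observed_sites):
                logger.info("genotype %s has %d < %d observed sites; "
                            "keeping all", g, len(observed_sites), keep_k)
        elif keep_k == 0:
            kept = []
        else:
            kept = list(rng.choice(observed_sites, size=keep_k,
                                   replace=False))
        hide_sites = [i for i in observed_sites if i not in kept]
        mask[j, hide_sites] = True
        for name, i in sur_cols.items():
            if name not in keep_surrogates and obs[j, i]:
                mask[j, i] = True
    return mask


@dataclass
class CVResult:
    """Per-(scenario, rep, fold, site) predictive abilities and summaries."""

    records: pd.DataFrame  # scenario, subpopulation, rep, fold, site, r, n_pairs
    n_fits: int = 0
    leakage_cells: int = 0

    def scenario_means(self) -> pd.Series:
        """Mean ability: sites -> folds -> replicates -> scenario."""
        df = self.records.dropna(subset=["r"])
        by_fold = (df.groupby(["scenario", "subpopulation", "rep", "fold"])
                   ["r"].mean())
        by_rep = by_fold.groupby(["scenario", "subpopulation", "rep"]).mean()
        by_sub = by_rep.groupby(["scenario", "subpopulation"]).mean()
        return by_sub.groupby("scenario").mean()

    def per_site_means(self) -> pd.DataFrame:
        df = self.records.dropna(subset=["r"])
        return (df.groupby(["scenario", "site"])["r"].mean().reset_index())


def predictive_ability(predictions: pd.DataFrame, response: ResponseMatrix,
                       scheme: CVScheme, min_pairs: int = 3) -> pd.DataFrame:
    """Per-site Pearson r between predicted and observed masked cells.

    Only biomass site columns are scored, and only cells that were masked
    out of this fold's training data. Sites with fewer than ``min_pairs``
    validation pairs are skipped (logged); zero-variance predictions give a
    missing r, never 0.
    """
    pred_map = {(g, c): v for g, c, v in zip(
        predictions["genotype_id"], predictions["column"],
        predictions["predicted"])}
    rows = []
    by_site: dict[str, list[tuple[float, float]]] = {}
    for (j, i) in scheme.score_cells:
        g = response.genotype_ids[j]
        c = response.column_labels[i]
        obs_val = response.values[j, i]
        if np.isnan(obs_val):
            continue
        by_site.setdefault(c, []).append((pred_map[(g, c)], obs_val))
    for site, pairs in sorted(by_site.items()):
        if len(pairs) < min_pairs:
            logger.info("site %s: %d pairs < %d, skipped", site, len(pairs),
                        min_pairs)
            continue
        p, o = np.array(pairs).T
        if np.std(p) == 0 or np.std(o) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(p, o)[0, 1])
        rows.append({"scenario": scheme.scenario,
                     "subpopulation": scheme.subpopulation,
                     "rep": scheme.replicate, "fold": scheme.fold,
                     "site": site, "r": r, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)


def plan_schemes(table: PhenotypeTable, scenarios: list[str],
                 folds: int = 8, reps: int = 5, seed: int = 0,
                 min_sites: int = 6, min_subpop: int = 60,
                 subpopulations: list[str] | None = None,
                 surrogate_sites: tuple[str, str] = ("KBSM", "CLMB")):
    """Enumerate every (scenario, subpopulation, rep, fold) fit with its mask.

    Pure bookkeeping — no model is fitted — so fold counts and leakage can be
    audited cheaply. Yields CVScheme objects.
    """
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    eligible = eligible_validation_set(table, min_sites, min_subpop)
    if subpopulations is not None:
        eligible = {s: g for s, g in eligible.items() if s in subpopulations}
    if not eligible:
        raise CVError("no subpopulation has enough eligible genotypes")
    genotypes_all = sorted(table.records["genotype_id"].unique())
    for scenario in scenarios:
        if scenario not in SCENARIOS:
            raise CVError(f"unknown scenario {scenario!r}")
        _, _, with_surrogates = SCENARIOS[scenario]
        surrogates = (("flowering_time", "fall_height")
                      if with_surrogates else ())
        response = build_response(table, surrogates=surrogates,
                                  surrogate_sites=surrogate_sites,
                                  scale=True, genotypes=genotypes_all)
        for subpop, members in sorted(eligible.items()):
            for rep in range(1, reps + 1):
                entropy = (seed, zlib.crc32(scenario.encode()),
                           zlib.crc32(subpop.encode()), rep)
                fold_seed, mask_seed = [
                    int(s.generate_state(1)[0] % (2 ** 31))
                    for s in np.random.SeedSequence(entropy).spawn(2)]
                fold_map = assign_folds(members, k=folds, seed=fold_seed)
                mask_rng = np.random.default_rng(mask_seed)
                for fold in range(1, folds + 1):
                    validation = [g for g, f in fold_map.items() if f == fold]
                    mask = build_training_mask(response, validation,
                                               scenario, mask_rng)
                    obs = response.observed_mask()
                    site_cols = [i for i, c in enumerate(response.column_labels)
                                 if c in response.site_columns]
                    row_of = {g: i for i, g in enumerate(response.genotype_ids)}
                    score = [(row_of[g], i) for g in validation
                             for i in site_cols
                             if obs[row_of[g], i] and mask[row_of[g], i]]
                    yield CVScheme(scenario, subpop, rep, fold, validation,
                                   mask, response, score)


def audit_scheme(scheme: CVScheme) -> int:
    """Count leakage cells: scored cells still visible in training data.

    Returns 0 for a sound scheme; every scored cell must be masked and every
    masked cell must be missing from the training response.
    """
    train = scheme.response.masked_copy(scheme.mask)
    leaks = 0
    for (j, i) in scheme.score_cells:
        if not scheme.mask[j, i] or not np.isnan(train.values[j, i]):
            leaks += 1
    return leaks


def run_scheme(table: PhenotypeTable, G: RelationshipMatrix,
               scenarios: list[str], folds: int = 8, reps: int = 5,
               seed: int = 0, n_iter: int = 3000, burn_in: int = 200,
               thin: int = 5, min_sites: int = 6, min_subpop: int = 60,
               subpopulations: list[str] | None = None,
               surrogate_sites: tuple[str, str] = ("KBSM", "CLMB"),
               min_pairs: int = 3) -> CVResult:
    """Full CV loop: mask -> Gibbs fit -> predict -> score, per scheme.

    With the default folds=8 and reps=5 this is 40 model fits per
    subpopulation per scenario.
    """
    all_rows = []
    n_fits = 0
    leakage = 0
    chain_ss = np.random.SeedSequence((seed, 0xC5))
    for scheme in plan_schemes(table, scenarios, folds, reps, seed,
                               min_sites, min_subpop, subpopulations,
                               surrogate_sites):
        leakage += audit_scheme(scheme)
        train = scheme.response.masked_copy(scheme.mask)
        chain_seed = int(chain_ss.spawn(1)[0].generate_state(1)[0] % 2 ** 31)
        post = run_gibbs(train, G, n_iter=n_iter, burn_in=burn_in,
                         thin=thin, seed=chain_seed)
        preds = predict_masked(post, scheme.mask)
        rows = predictive_ability(preds, scheme.response, scheme, min_pairs)
        all_rows.append(rows)
        n_fits += 1
    if leakage:
        raise CVError(f"training/validation leakage detected: {leakage} cells")
    records = (pd.concat(all_rows, ignore_index=True) if all_rows
               else pd.DataFrame(columns=["scenario", "subpopulation", "rep",
                                          "fold", "site", "r", "n_pairs"]))
    return CVResult(records, n_fits=n_fits, leakage_cells=leakage)
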