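"""REML GBLUP: variance components, BLUPs, correlations, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import gxepred as gp
from gxepred.gblup import FitError, MultiTraitFit, _cullis_vbar_from_cgg
from gxepred.markers import RelationshipMatrix
from gxepred.pheno import PhenotypeTable
from gxepred.simulate import DEFAULT_SITES, SimulationConfig, simulate_dataset

from conftest import random_grm


def _single_site_table(ids, Y, traits):
    recs = [(g, "S1", tr, float(Y[i, k]) + 100.0)
            for k, tr in enumerate(traits) for i, g in enumerate(ids)]
    rec = pd.DataFrame(recs, columns=["genotype_id", "site", "trait", "value"])
    return PhenotypeTable(rec.assign(year=None), aggregated=True)


def _fit_stub(traits, ta, vbar):
    t = len(traits)
    return MultiTraitFit(
        traits=traits, genotype_ids=["a", "b"],
        fixed_effects=pd.DataFrame(), Ta=pd.DataFrame(ta, index=traits,
                                                      columns=traits),
        residual_var=pd.Series(1.0, index=traits),
        blups=pd.DataFrame(0.0, index=["a", "b"], columns=traits),
        pev=pd.DataFrame(0.0, index=["a", "b"], columns=traits),
        cullis_vbar=pd.Series(vbar, index=traits),
        loglik=0.0, converged=True, n_iter=1, method="stub")


class TestGeneticCorrelations:
    def test_arithmetic(self):
        fit = _fit_stub(["biomass", "fall_height"],
                        np.array([[4.0, 2.0], [2.0, 4.0]]), [0.1, 0.1])
        r = gp.genetic_correlations(fit)
        assert r.loc["biomass", "fall_height"] == pytest.approx(0.5)
        assert r.loc["biomass", "biomass"] == 1.0

    def test_diagonal_ta_gives_identity(self):
        fit = _fit_stub(["a", "b", "c"], np.diag([1.0, 2.0, 3.0]),
                        [0.1, 0.1, 0.1])
        np.testing.assert_allclose(gp.genetic_correlations(fit).to_numpy(),
                                   np.eye(3))

    def test_zero_variance_trait_missing_with_warning(self):
        fit = _fit_stub(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]),
                        [0.1, 0.1])
        with pytest.warns(UserWarning, match="zero genetic variance"):
            r = gp.genetic_correlations(fit)
        assert np.isnan(r.loc["a", "b"])


class TestHeritability:
    def test_zero_pev_limit_gives_one(self):
        fit = _fit_stub(["biomass"], np.array([[2.0]]), [0.0])
        assert gp.heritability(fit, "biomass") == pytest.approx(1.0)

    def test_zero_genetic_variance_gives_zero(self):
        fit = _fit_stub(["biomass"], np.array([[0.0]]), [0.5])
        with pytest.warns(UserWarning):
            assert gp.heritability(fit, "biomass") == 0.0

    def test_cullis_vbar_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        cgg = a @ a.T
        n = 5
        pairs = [cgg[i, i] + cgg[j, j] - 2 * cgg[i, j]
                 for i in range(n) for j in range(i + 1, n)]
        assert _cullis_vbar_from_cgg(cgg) == pytest.approx(np.mean(pairs))


def _direct_reml_nll(G, X, Z, y):
    """Independent REML objective via the full covariance V (test oracle)."""
    n = len(y)
    ridge = 1e-6 * np.mean(np.diag(G))
    greg = G + ridge * np.eye(G.shape[0])

    def nll(logpars):
        sg2, se2 = np.exp(logpars)
        v = sg2 * Z @ greg @ Z.T + se2 * np.eye(n)
        _, ldv = np.linalg.slogdet(v)
        vi = np.linalg.inv(v)
        xvx = X.T @ vi @ X
        _, ldx = np.linalg.slogdet(xvx)
        b = np.linalg.solve(xvx, X.T @ vi @ y)
        r = y - X @ b
        return ldv + ldx + r @ vi @ r

    return nll


class TestREMLOracle:
    def test_em_matches_profile_likelihood_grid(self):
        """Balanced 12-genotype instance: EM-REML vs grid + polish oracle."""
        rng = np.random.default_rng(42)
        n = 12
        G = random_grm(rng, n, 100)
        ids = [f"g{i}" for i in range(n)]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n) * np.sqrt(2.0)
        recs, rows_x, rows_z, yv = [], [], [], []
        for si, (s, off) in enumerate([("A", 20.0), ("B", 22.0)]):
            y = off + u + rng.standard_normal(n)
            for i, g in enumerate(ids):
                recs.append((g, s, "biomass", float(y[i])))
                rows_x.append([1, 0] if si == 0 else [0, 1])
                rows_z.append(i)
                yv.append(y[i])
        table = PhenotypeTable(pd.DataFrame(
            recs, columns=["genotype_id", "site", "trait", "value"]).assign(
            year=None), aggregated=True)
        X = np.array(rows_x, float)
        Z = np.zeros((2 * n, n))
        Z[np.arange(2 * n), rows_z] = 1.0
        nll = _direct_reml_nll(G, X, Z, np.array(yv))
        best = min(((nll([a, b]), [a, b])
                    for a in np.linspace(-3, 3, 25)
                    for b in np.linspace(-3, 3, 25)), key=lambda t: t[0])
        res = minimize(nll, best[1], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        sg2_o, se2_o = np.exp(res.x)
        fit = gp.fit_gblup(table, RelationshipMatrix(ids, G))
        assert fit.Ta.iloc[0, 0] == pytest.approx(sg2_o, abs=1e-4)
        assert fit.residual_var.iloc[0] == pytest.approx(se2_o, abs=1e-4)

    def test_em_loglik_nondecreasing(self, tiny_data):
        fit = gp.fit_gblup(tiny_data["agg"], tiny_data["G"],
                           ["biomass", "fall_height"])
        assert fit.method == "em-mme"
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) > -1e-7 * np.abs(trace[:-1]))

    def test_fast_and_general_paths_agree(self):
        """Single-site data: eigen-rotated NM vs MME EM on the same REML."""
        rng = np.random.default_rng(5)
        n = 60
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        Y = (L @ rng.standard_normal(n))[:, None] + \
            rng.standard_normal((n, 1)) * 0.8
        table = _single_site_table(ids, Y, ["biomass"])
        grm = RelationshipMatrix(ids, G)
        fast = gp.fit_gblup(table, grm)
        assert fast.method == "eigen-nm"
        # run the general EM machinery on the identical records
        from gxepred import gblup as gb
        rec, gsub, genos = gb._prepare(table, grm, ["biomass"])
        out = gb._fit_em(rec, gsub, ["biomass"], genos, tol=1e-7,
                         max_iter=1000)
        assert out["ta"][0, 0] == pytest.approx(fast.Ta.iloc[0, 0], abs=1e-3)
        assert out["se2"][0] == pytest.approx(fast.residual_var.iloc[0],
                                              abs=1e-3)
        np.testing.assert_allclose(out["blups"][:, 0],
                                   fast.blups["biomass"].to_numpy(),
                                   atol=1e-3)

    def test_pev_matches_direct_mme_oracle(self):
        """From-scratch mixed-model-equation PEV at the converged components."""
        rng = np.random.default_rng(9)
        n = 8
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n) * 1.2
        recs = []
        for s, off in [("A", 20.0), ("B", 21.0)]:
            y = off + u + rng.standard_normal(n) * 0.8
            recs.extend((ids[i], s, "biomass", float(y[i])) for i in range(n))
        table = PhenotypeTable(pd.DataFrame(
            recs, columns=["genotype_id", "site", "trait", "value"]).assign(
            year=None), aggregated=True)
        fit = gp.fit_gblup(table, RelationshipMatrix(ids, G))
        sg2 = float(fit.Ta.iloc[0, 0])
        se2 = float(fit.residual_var.iloc[0])
        # direct MME with the fitted components
        X = np.kron(np.eye(2), np.ones((n, 1)))
        Z = np.vstack([np.eye(n), np.eye(n)])
        ridge = 1e-6 * np.mean(np.diag(G))
        ginv = np.linalg.inv(G + ridge * np.eye(n))
        top = np.hstack([X.T @ X / se2, X.T @ Z / se2])
        bot = np.hstack([Z.T @ X / se2, Z.T @ Z / se2 + ginv / sg2])
        C = np.linalg.inv(np.vstack([top, bot]))
        pev_oracle = np.diag(C)[2:]
        np.testing.assert_allclose(fit.pev["biomass"].to_numpy(), pev_oracle,
                                   rtol=1e-5)


class TestSimulationChecks:
    def test_null_heritability_near_zero(self):
        """Phenotype independent of G: variance ratio below 0.05."""
        rng = np.random.default_rng(17)
        n = 200
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        Y = rng.standard_normal((n, 1)) * 2.0
        fit = gp.fit_gblup(_single_site_table(ids, Y, ["biomass"]),
                           RelationshipMatrix(ids, G))
        sg2 = float(fit.Ta.iloc[0, 0])
        assert sg2 / (sg2 + float(fit.residual_var.iloc[0])) < 0.05

    def test_duplicated_trait_correlation_near_one(self):
        rng = np.random.default_rng(19)
        n = 120
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        g = L @ rng.standard_normal(n)
        y = g + rng.standard_normal(n) * 0.5
        Y = np.column_stack([y, y + rng.standard_normal(n) * 0.01])
        fit = gp.fit_gblup(_single_site_table(ids, Y,
                                              ["biomass", "fall_height"]),
                           RelationshipMatrix(ids, G))
        r = gp.genetic_correlations(fit)
        assert r.loc["biomass", "fall_height"] > 0.99

    def test_parameter_recovery_bias(self):
        """20 replicates at n=500: |mean bias| of h2-ratio and r_g < 0.05."""
        h2r, rgh = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                n_per_subpop={"Texas": 125, "Coastal": 125, "Midwest": 125,
                              "Gulf": 125},
                n_markers=1500,
                sites=DEFAULT_SITES[DEFAULT_SITES.site == "KBSM"]
                .reset_index(drop=True),
                seed=300 + seed)
            _, _, G, table, _ = simulate_dataset(cfg)
            agg = gp.aggregate_phenotypes(table)
            fit = gp.fit_gblup(agg, G, ["biomass", "fall_height"])
            ta = fit.Ta.loc["biomass", "biomass"]
            h2r.append(ta / (ta + fit.residual_var["biomass"]))
            rgh.append(gp.genetic_correlations(fit)
                       .loc["biomass", "fall_height"])
        assert abs(np.mean(h2r) - 0.6) < 0.05
        assert abs(np.mean(rgh) - 0.85) < 0.05

    def test_multitrait_beats_single_trait_heritability(self):
        """Paired one-sided comparison over 20 replicates (Wilcoxon)."""
        from scipy.stats import wilcoxon
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_per_subpop={"Texas": 38, "Coastal": 38, "Midwest": 37,
                              "Gulf": 37},
                n_markers=800,
                sites=DEFAULT_SITES[DEFAULT_SITES.site == "CLMB"]
                .reset_index(drop=True),
                seed=700 + seed)
            _, _, G, table, _ = simulate_dataset(cfg)
            agg = gp.aggregate_phenotypes(table)
            fm = gp.fit_gblup(agg, G,
                              ["biomass", "fall_height", "flowering_time"])
            fs = gp.fit_gblup(agg, G, ["biomass"])
            diffs.append(gp.heritability(fm, "biomass")
                         - gp.heritability(fs, "biomass"))
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.05


class TestErrors:
    def test_non_psd_g_rejected(self):
        ids = ["a", "b"]
        g = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        table = _single_site_table(ids, np.array([[1.0], [2.0]]), ["biomass"])
        with pytest.raises(FitError, match="bend"):
            gp.fit_gblup(table, RelationshipMatrix(ids, g))

    def test_zero_variance_trait_rejected(self):
        rng = np.random.default_rng(3)
        n = 10
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        Y = np.zeros((n, 1))
        with pytest.raises(FitError, match="zero variance"):
            gp.fit_gblup(_single_site_table(ids, Y, ["biomass"]),
                         RelationshipMatrix(ids, G))

    def test_genotype_missing_from_g_rejected(self):
        rng = np.random.default_rng(4)
        n = 5
        G = random_grm(rng, n)
        ids = [f"g{i}" for i in range(n)]
        Y = rng.standard_normal((n, 1))
        table = _single_site_table([f"x{i}" for i in range(n)], Y, ["biomass"])
        with pytest.raises(FitError, match="absent from G"):
            gp.fit_gblup(table, RelationshipMatrix(ids, G))
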