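"""Bayesian multivariate Gaussian prediction with Kronecker genetic covariance.

Sites (and optional yield-surrogate traits) enter as correlated response
columns of an n_genotypes x t matrix Y. The model per column i is

    y_i = mu_i 1 + g_i + e_i,    vec(g) ~ MVN(0, Ta (x) G),
    e_i ~ N(0, I sigma2_e[i]),

with Ta the unstructured t x t genetic covariance among columns and G the
genomic relationship matrix. Priors: Ta ~ inverse-Wishart(nu = t + 2,
S = 0.5 nu I), per-column residuals ~ scaled-inv-chi2(df = 5, scale = 0.5),
flat priors on intercepts — weakly informative defaults on the standardized
scale.

Sampling is done in the eigenbasis of G (G = U D U'): the full conditional of
the rotated breeding values factorizes over eigencomponents into independent
t x t Gaussian solves, so no nt x nt matrix is ever formed. Missing response
cells are Gibbs-augmented — each sweep draws them from their full
conditional N(mu_i + g_ji, sigma2_e[i]) — which leaves the marginal posterior
given the observed cells unchanged while keeping every full conditional in
closed form. Predictions for masked cells are posterior means mu_i + gbar_ji
on the standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import RelationshipMatrix
from .pheno import PhenotypeTable, aggregate_phenotypes, surrogate_site_means

logger = logging.getLogger(__name__)


class GibbsError(RuntimeError):
    pass


def n_retained(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of retained draws for a chain plan: floor((n_iter-burn)/thin)."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return (n_iter - burn_in) // thin


@dataclass
class ResponseMatrix:
    """Genotypes x response-columns matrix with missing cells as NaN."""

    genotype_ids: list[str]
    column_labels: list[str]
    values: np.ndarray
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    #: column labels that are biomass sites (as opposed to surrogate traits)
    site_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids),
                                 len(self.column_labels)):
            raise ValueError("shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def masked_copy(self, mask: np.ndarray) -> "ResponseMatrix":
        """Return a copy with cells where ``mask`` is True set to missing."""
        vals = self.values.copy()
        vals[mask] = np.nan
        return ResponseMatrix(list(self.genotype_ids),
                              list(self.column_labels), vals,
                              self.scale_mean, self.scale_sd,
                              list(self.site_columns))


def build_response(table: PhenotypeTable, sites: list[str] | None = None,
                   surrogates: tuple[str, ...] = (),
                   surrogate_sites: tuple[str, str] = ("KBSM", "CLMB"),
                   scale: bool = True,
                   genotypes: list[str] | None = None) -> ResponseMatrix:
    """One biomass column per site plus one column per requested surrogate.

    Surrogate columns are per-genotype means of the surrogate trait over
    ``surrogate_sites`` (a single cheap measurement standing in for yield).
    Columns with fewer than 2 observed values are dropped with a warning.
    When ``scale`` is set, each column is standardized to mean 0, sd 1 over
    its observed cells.
    """
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    rec = table.records
    bio = rec[rec["trait"] == "biomass"]
    wide = bio.pivot(index="genotype_id", columns="site", values="value")
    if sites is not None:
        wide = wide.reindex(columns=[s for s in sites if s in wide.columns])
    if genotypes is None:
        genotypes = sorted(rec["genotype_id"].unique())
    wide = wide.reindex(index=genotypes)
    site_cols = [str(c) for c in wide.columns]
    cols = {str(c): wide[c] for c in wide.columns}
    for sur in surrogates:
        vals = surrogate_site_means(table, surrogate_sites, trait=sur)
        cols[sur] = vals.reindex(genotypes)
    mat = pd.DataFrame(cols, index=genotypes)
    keep = mat.notna().sum(axis=0) >= 2
    if not keep.all():
        logger.warning("dropping response columns with <2 observations: %s",
                       list(mat.columns[~keep]))
        mat = mat.loc[:, keep]
        site_cols = [c for c in site_cols if c in mat.columns]
    values = mat.to_numpy(dtype=float)
    mean = sd = None
    if scale:
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        values = (values - mean) / sd
    return ResponseMatrix(list(genotypes), [str(c) for c in mat.columns],
                          values, mean, sd, site_cols)


@dataclass
class GibbsPosterior:
    genotype_ids: list[str]
    column_labels: list[str]
    g_mean: np.ndarray          # posterior mean breeding values, n x t
    mu_mean: np.ndarray         # posterior mean intercepts, t
    ta_draws: np.ndarray        # retained x t x t
    sigma2_draws: np.ndarray    # retained x t
    mu_draws: np.ndarray        # retained x t
    n_iter: int
    burn_in: int
    thin: int
    seed: int

    @property
    def n_retained(self) -> int:
        return self.ta_draws.shape[0]

    def ta_mean(self) -> np.ndarray:
        return self.ta_draws.mean(axis=0)

    def split_rhat(self) -> np.ndarray:
        """Split-Rhat on the Ta diagonal draws (rough convergence check)."""
        diags = np.einsum("rii->ri", self.ta_draws)
        m = diags.shape[0] // 2
        if m < 2:
            return np.full(diags.shape[1], np.nan)
        halves = np.stack([diags[:m], diags[m:2 * m]])
        w = halves.var(axis=1, ddof=1).mean(axis=0)
        b = m * halves.mean(axis=1).var(axis=0, ddof=1)
        var_plus = (m - 1) / m * w + b / m
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(var_plus / w)

    def summary(self) -> dict:
        return {
            "columns": self.column_labels,
            "n_retained": int(self.n_retained),
            "Ta_mean": self.ta_mean().tolist(),
            "residual_var_mean": self.sigma2_draws.mean(axis=0).tolist(),
            "split_rhat_Ta_diag": self.split_rhat().tolist(),
            "chain": {"n_iter": self.n_iter, "burn_in": self.burn_in,
                      "thin": self.thin, "seed": self.seed},
        }


def run_gibbs(Y: ResponseMatrix, G: RelationshipMatrix, n_iter: int = 3000,
              burn_in: int = 200, thin: int = 5, seed: int = 0,
              fix_ta: np.ndarray | None = None,
              fix_sigma2: np.ndarray | None = None) -> GibbsPosterior:
    """Gibbs sampler for the Kronecker-covariance multisite model.

    ``fix_ta`` / ``fix_sigma2`` pin the genetic covariance and residual
    variances at known values instead of sampling them (calibration and
    equivalence checks against BLUP).
    """
    if Y.t < 2:
        raise GibbsError("need at least 2 response columns")
    n_keep = n_retained(n_iter, burn_in, thin)
    gsub = G.subset(Y.genotype_ids)
    if gsub.min_eigenvalue() < -1e-8:
        raise GibbsError("G is not positive semidefinite; bend it first")

    rng = np.random.default_rng(seed)
    n, t = Y.n, Y.t
    obs = Y.observed_mask()
    if not obs.any(axis=0).all():
        raise GibbsError("a response column has no observed cells")

    d, u = np.linalg.eigh(gsub.values)
    d = np.clip(d, 1e-8, None)
    dinv = 1.0 / d

    # priors
    nu0 = t + 2
    s0 = 0.5 * nu0 * np.eye(t)
    df_e, scale_e = 5.0, 0.5

    # initial state
    mu = np.where(obs.any(axis=0), np.nanmean(Y.values, axis=0), 0.0)
    g = np.zeros((n, t))
    ta = 0.5 * np.eye(t) if fix_ta is None else np.asarray(fix_ta, float)
    se2 = (np.full(t, 0.5) if fix_sigma2 is None
           else np.asarray(fix_sigma2, float))
    ycomp = Y.values.copy()
    ycomp[~obs] = np.broadcast_to(mu, (n, t))[~obs]

    g_sum = np.zeros((n, t))
    mu_sum = np.zeros(t)
    ta_draws = np.empty((n_keep, t, t))
    se2_draws = np.empty((n_keep, t))
    mu_draws = np.empty((n_keep, t))
    kept = 0

    eye_t = np.arange(t)
    for it in range(1, n_iter + 1):
        # (a) intercepts (flat prior)
        resid_mean = (ycomp - g).mean(axis=0)
        mu = resid_mean + rng.standard_normal(t) * np.sqrt(se2 / n)

        # (b) breeding values in the eigenbasis of G
        ta_inv = np.linalg.inv(ta)
        ytil = u.T @ (ycomp - mu)
        prec = (ta_inv[None] * dinv[:, None, None]
                + np.diag(1.0 / se2)[None])                    # (n, t, t)
        cf = np.linalg.cholesky(prec)
        rhs = ytil / se2
        mean_rot = np.linalg.solve(prec, rhs[..., None])[..., 0]
        z = rng.standard_normal((n, t, 1))
        dev = np.linalg.solve(np.transpose(cf, (0, 2, 1)), z)[..., 0]
        g_rot = mean_rot + dev
        g = u @ g_rot

        # (c) genetic covariance Ta ~ inverse-Wishart full conditional
        if fix_ta is None:
            s_post = s0 + g_rot.T @ (g_rot * dinv[:, None])
            s_post = (s_post + s_post.T) / 2.0
            ta = stats.invwishart.rvs(df=nu0 + n, scale=s_post,
                                      random_state=rng)
            ta = np.atleast_2d(ta)

        # (d) residual variances, scaled-inverse-chi-square
        if fix_sigma2 is None:
            resid = ycomp - mu - g
            ssr = np.sum(resid * resid, axis=0)
            df_post = df_e + n
            scale_post = (df_e * scale_e + ssr) / df_post
            se2 = df_post * scale_post / rng.chisquare(df_post, size=t)

        # (e) augment missing cells
        miss = ~obs
        if miss.any():
            noise = rng.standard_normal(ycomp.shape)
            filled = mu + g + noise * np.sqrt(se2)
            ycomp[miss] = filled[miss]

        if not np.all(np.isfinite(g)):
            raise GibbsError(f"divergent chain at iteration {it}")

        if it > burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            g_sum += g
            mu_sum += mu
            ta_draws[kept] = ta
            se2_draws[kept] = se2
            mu_draws[kept] = mu
            kept += 1

    return GibbsPosterior(list(Y.genotype_ids), list(Y.column_labels),
                          g_sum / kept, mu_sum / kept, ta_draws[:kept],
                          se2_draws[:kept], mu_draws[:kept],
                          n_iter, burn_in, thin, seed)


def predict_masked(post: GibbsPosterior, mask: np.ndarray) -> pd.DataFrame:
    """Predicted values for masked cells: posterior mean mu_i + g[j, i].

    ``mask`` is a boolean n x t array (True = cell to predict). Returns a tidy
    frame (genotype, column, predicted) on the standardized scale.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != post.g_mean.shape:
        raise ValueError("mask shape does not match posterior")
    pred = post.mu_mean[None, :] + post.g_mean
    jj, ii = np.nonzero(mask)
    return pd.DataFrame({
        "genotype_id": [post.genotype_ids[j] for j in jj],
        "column": [post.column_labels[i] for i in ii],
        "predicted": pred[jj, ii],
    })
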