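"""Single- and multitrait genomic mixed models (GBLUP) fitted by REML.

Model, per trait t and record r:

    y_r = s_{site(r), t} + g_{geno(r), t} + e_r,

with genotype effects across traits g ~ MVN(0, Ta (x) G) for an unstructured
t x t genetic covariance Ta and the marker-based relationship matrix G, and
independent residuals e_r ~ N(0, sigma2_e[t]) (diagonal residual covariance
across traits). Site effects are fixed (cell-means coding per trait).

Two REML paths maximize the same objective:

* a general EM-REML on the mixed-model equations (Aitken-accelerated) for
  arbitrary unbalanced designs, and
* an exact eigen-rotated likelihood maximized derivative-free when every
  genotype has exactly one record per trait at a single site (genotype-mean
  data); in the eigenbasis of G the likelihood factorizes over components
  and each evaluation costs O(n t^3).

Derived quantities: genetic correlations r_ab = Ta_ab / sqrt(Ta_aa Ta_bb) and
generalized (Cullis) heritability on a genotype-difference basis,
H2 = 1 - vbar_delta / (2 sigma2_g), with vbar_delta the mean prediction-error
variance of a BLUP difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .markers import RelationshipMatrix
from .pheno import PhenotypeTable, aggregate_phenotypes

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


class ConvergenceError(FitError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class MultiTraitFit:
    traits: list[str]
    genotype_ids: list[str]
    fixed_effects: pd.DataFrame       # columns: trait, site, estimate
    Ta: pd.DataFrame                  # t x t genetic covariance
    residual_var: pd.Series           # per trait
    blups: pd.DataFrame               # genotypes x traits
    pev: pd.DataFrame                 # genotypes x traits
    cullis_vbar: pd.Series            # mean BLUP-difference variance per trait
    loglik: float
    converged: bool
    n_iter: int
    method: str
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def genetic_correlations(fit: MultiTraitFit) -> pd.DataFrame:
    """Convert the genetic covariance Ta to a correlation matrix.

    Traits with (numerically) zero genetic variance get missing correlations
    with a warning; the diagonal is exactly 1 where defined.
    """
    if fit.n_traits < 2:
        raise ValueError("need a multitrait fit (t >= 2)")
    ta = fit.Ta.to_numpy()
    sd = np.sqrt(np.clip(np.diag(ta), 0, None))
    bad = sd <= 1e-12 * max(1.0, float(np.max(np.abs(ta))))
    if bad.any():
        warnings.warn("zero genetic variance for "
                      f"{[t for t, b in zip(fit.traits, bad) if b]}: "
                      "correlations undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ta / np.outer(sd, sd)
    np.fill_diagonal(r, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=fit.traits, columns=fit.traits)


def heritability(fit: MultiTraitFit, trait: str) -> float:
    """Cullis generalized heritability H2 = 1 - vbar_delta / (2 sigma2_g)."""
    sg2 = float(fit.Ta.loc[trait, trait])
    if sg2 <= 0:
        warnings.warn(f"zero genetic variance for {trait}: heritability 0")
        return 0.0
    vbar = float(fit.cullis_vbar[trait])
    return float(np.clip(1.0 - vbar / (2.0 * sg2), 0.0, 1.0))


# ---------------------------------------------------------------------------
# data preparation


def _check_g(G: RelationshipMatrix, psd_tol: float = 1e-8) -> None:
    if G.min_eigenvalue() < -psd_tol:
        raise FitError("G is not positive semidefinite; bend it first "
                       "(markers.realized_relationship applies bending)")


def _prepare(table: PhenotypeTable, G: RelationshipMatrix, traits):
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    rec = table.records
    rec = rec[rec["trait"].isin(traits)]
    if rec.empty:
        raise FitError("no records for requested traits")
    genos = sorted(rec["genotype_id"].unique())
    missing = set(genos) - set(G.individual_ids)
    if missing:
        raise FitError(f"phenotyped genotypes absent from G: "
                       f"{sorted(missing)[:5]}")
    for t in traits:
        v = rec.loc[rec["trait"] == t, "value"]
        if len(v) < 2 or float(np.var(v)) <= 0:
            raise FitError(f"trait {t!r} has zero variance or too few records")
    gsub = G.subset(genos)
    return rec, gsub, genos


def _cullis_vbar_from_cgg(cgg: np.ndarray) -> float:
    """Mean variance of a BLUP difference from the PEV block C_gg."""
    n = cgg.shape[0]
    a = float(np.trace(cgg))
    s = float(cgg.sum())
    return 2.0 * (n * a - s) / (n * (n - 1))


# ---------------------------------------------------------------------------
# general EM-REML on the mixed-model equations


def _fit_em(rec, G, traits, genos, tol, max_iter):
    t = len(traits)
    ng = len(genos)
    gidx = {g: i for i, g in enumerate(genos)}
    tidx = {tr: i for i, tr in enumerate(traits)}

    # fixed-effect columns: one per (trait, site) combination actually observed
    combos = sorted({(row.trait, row.site)
                     for row in rec.itertuples(index=False)})
    fidx = {c: i for i, c in enumerate(combos)}
    nf = len(combos)

    y = rec["value"].to_numpy(dtype=float)
    r_t = rec["trait"].map(tidx).to_numpy()
    r_f = np.array([fidx[(tr, s)] for tr, s in zip(rec["trait"], rec["site"])])
    r_g = rec["genotype_id"].map(gidx).to_numpy()
    r_u = nf + r_t * ng + r_g  # genotype-effect column (trait-major)
    dim = nf + t * ng
    n_t = np.bincount(r_t, minlength=t).astype(float)

    # trait-wise crossproducts, computed once (R^-1 scaling applied per iter)
    ff = np.zeros((t, nf))
    np.add.at(ff, (r_t, r_f), 1.0)
    fg_rows, fg_cols = r_f, r_u
    fy = np.zeros((t, nf))
    np.add.at(fy, (r_t, r_f), y)
    uy = np.zeros(dim)
    np.add.at(uy, r_u, y)
    yy_t = np.zeros(t)
    np.add.at(yy_t, r_t, y * y)

    # the centered-crossproduct G is singular (null vector 1); a small ridge
    # relative to the mean diagonal makes the prior proper without
    # perceptibly changing the fit
    ridge = 1e-6 * float(np.mean(np.diag(G.values)))
    greg = G.values + ridge * np.eye(ng)
    ginv = np.linalg.inv(greg)
    ginv = (ginv + ginv.T) / 2.0
    _, logdet_g = np.linalg.slogdet(greg)

    # starting values: split phenotypic variance in half
    var_p = np.array([float(np.var(y[r_t == i])) for i in range(t)])
    ta = np.diag(0.5 * var_p)
    se2 = 0.5 * var_p

    def pack(ta, se2):
        iu = np.triu_indices(t)
        return np.concatenate([ta[iu], se2])

    def solve_mme(ta, se2):
        rinv = 1.0 / se2
        m = np.zeros((dim, dim))
        # F'R^-1F (diagonal: counts per fixed column, single trait each)
        diag_f = (ff * rinv[:, None]).sum(axis=0)
        m[np.arange(nf), np.arange(nf)] = diag_f
        # F'R^-1Z and Z'R^-1Z
        np.add.at(m, (fg_rows, fg_cols), rinv[r_t])
        np.add.at(m, (fg_cols, fg_rows), rinv[r_t])
        d = np.zeros(dim)
        np.add.at(d, r_u, rinv[r_t])
        m[np.arange(dim), np.arange(dim)] += d * (np.arange(dim) >= nf)
        # prior precision on genotype effects
        ta_inv = np.linalg.inv(ta)
        m[nf:, nf:] += np.kron(ta_inv, ginv)
        rhs = np.concatenate([(fy * rinv[:, None]).sum(axis=0),
                              uy[nf:] * np.repeat(rinv, ng)])
        cf = cho_factor(m, lower=True)
        theta = cho_solve(cf, rhs)
        cinv = cho_solve(cf, np.eye(dim))
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return theta, cinv, rhs, logdet_m, ta_inv

    def reml_ll(ta, se2, theta, rhs, logdet_m):
        ypy = float(np.sum(yy_t / se2)) - float(theta @ rhs)
        _, logdet_ta = np.linalg.slogdet(ta)
        return -0.5 * (float(n_t @ np.log(se2)) + ng * logdet_ta
                       + t * logdet_g + logdet_m + ypy)

    trace = []
    params_hist = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta, cinv, rhs, logdet_m, _ = solve_mme(ta, se2)
        trace.append(reml_ll(ta, se2, theta, rhs, logdet_m))

        # EM updates
        uhat = theta[nf:].reshape(t, ng)
        ta_new = np.empty((t, t))
        for a in range(t):
            for b in range(a, t):
                cab = cinv[nf + a * ng:nf + (a + 1) * ng,
                           nf + b * ng:nf + (b + 1) * ng]
                val = (uhat[a] @ ginv @ uhat[b] + np.sum(ginv * cab.T)) / ng
                ta_new[a, b] = ta_new[b, a] = val
        ehat = y - theta[r_f] - theta[r_u]
        tr_t = (cinv[r_f, r_f] + 2.0 * cinv[r_f, r_u] + cinv[r_u, r_u])
        se2_new = np.zeros(t)
        np.add.at(se2_new, r_t, ehat * ehat + tr_t)
        se2_new /= n_t

        v_old, v_new = pack(ta, se2), pack(ta_new, se2_new)
        params_hist.append(v_new)
        # scale-aware relative change: components collapsing to the zero
        # boundary should not stall convergence
        scale = 1e-6 * float(np.max(var_p))
        rel = np.max(np.abs(v_new - v_old) / np.maximum(np.abs(v_new), scale))
        ta, se2 = ta_new, se2_new

        # Aitken extrapolation every 4th step once a history exists
        if it % 4 == 0 and len(params_hist) >= 3:
            v0, v1, v2 = params_hist[-3], params_hist[-2], params_hist[-1]
            d1, d2 = v1 - v0, v2 - v1
            denom = float(d1 @ d1)
            if denom > 0:
                rate = float(d2 @ d1) / denom
                if 0.0 < rate < 0.9999:
                    mult = min(rate / (1.0 - rate), 100.0)
                    v_acc = v2 + d2 * mult
                    ta_acc = np.zeros((t, t))
                    iu = np.triu_indices(t)
                    ta_acc[iu] = v_acc[:len(iu[0])]
                    ta_acc = ta_acc + np.triu(ta_acc, 1).T
                    se2_acc = v_acc[len(iu[0]):]
                    if (np.all(se2_acc > 0)
                            and np.all(np.linalg.eigvalsh(ta_acc) > 0)):
                        ta, se2 = ta_acc, se2_acc
        if rel < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} iterations", trace=trace)

    theta, cinv, rhs, logdet_m, _ = solve_mme(ta, se2)
    ll = reml_ll(ta, se2, theta, rhs, logdet_m)
    uhat = theta[nf:].reshape(t, ng)
    pev = np.empty((ng, t))
    vbar = {}
    for a, tr in enumerate(traits):
        cgg = cinv[nf + a * ng:nf + (a + 1) * ng,
                   nf + a * ng:nf + (a + 1) * ng]
        pev[:, a] = np.diag(cgg)
        vbar[tr] = _cullis_vbar_from_cgg(cgg)
    fixed = pd.DataFrame([{"trait": tr, "site": s, "estimate": theta[fidx[(tr, s)]]}
                          for (tr, s) in combos])
    return dict(fixed=fixed, ta=ta, se2=se2, blups=uhat.T, pev=pev,
                vbar=vbar, loglik=ll, n_iter=it, trace=trace,
                converged=True, method="em-mme")


# ---------------------------------------------------------------------------
# fast path: complete genotype-mean data, exact eigen-rotated REML


def _nll_rotated(params, t, d, ytil, xtil):
    """-2 x REML log-likelihood in the eigenbasis of G (up to a constant)."""
    iu = np.tril_indices(t)
    L = np.zeros((t, t))
    L[iu] = params[:len(iu[0])]
    ld = np.arange(t)
    L[ld, ld] = np.exp(np.clip(np.diag(L), -20, 20))
    ta = L @ L.T
    se2 = np.exp(np.clip(params[len(iu[0]):], -30, 30))
    v = d[:, None, None] * ta[None] + np.diag(se2)[None]     # (n, t, t)
    try:
        cf = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.log(np.einsum("kii->ki", cf)).sum()
    vinv = np.linalg.inv(v)
    a = np.einsum("k,kab->ab", xtil ** 2, vinv)
    b = np.einsum("k,kab,kb->a", xtil, vinv, ytil)
    try:
        beta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return 1e12
    r = ytil - xtil[:, None] * beta[None, :]
    quad = np.einsum("ka,kab,kb->", r, vinv, r)
    sgn, logdet_a = np.linalg.slogdet(a)
    if sgn <= 0:
        return 1e12
    return float(logdet + logdet_a + quad)


def _fit_eigen(Y, G, traits, genos):
    n, t = Y.shape
    d, u = np.linalg.eigh(G.values)
    d = np.clip(d, 1e-10, None)
    ytil = u.T @ Y
    xtil = u.T @ np.ones(n)

    cov0 = np.cov(Y.T).reshape(t, t)
    ta0 = 0.5 * cov0 + 1e-6 * np.eye(t) * np.trace(cov0)
    L0 = np.linalg.cholesky(ta0)
    iu = np.tril_indices(t)
    # pack L with log-transformed diagonal so positivity is unconstrained
    L0p = L0.copy()
    L0p[np.arange(t), np.arange(t)] = np.log(np.diag(L0))
    p0 = np.concatenate([L0p[iu], np.log(0.5 * np.diag(cov0))])

    res = optimize.minimize(
        _nll_rotated, p0, args=(t, d, ytil, xtil), method="Nelder-Mead",
        options={"maxiter": 1500 * len(p0), "xatol": 1e-9, "fatol": 1e-11})
    if not res.success:  # one restart from a perturbed point
        res2 = optimize.minimize(
            _nll_rotated, res.x + 0.1, args=(t, d, ytil, xtil),
            method="Nelder-Mead",
            options={"maxiter": 1500 * len(p0), "xatol": 1e-9,
                     "fatol": 1e-11})
        if res2.fun < res.fun:
            res = res2

    L = np.zeros((t, t))
    L[iu] = res.x[:len(iu[0])]
    L[np.arange(t), np.arange(t)] = np.exp(np.diag(L))
    ta = L @ L.T
    se2 = np.exp(res.x[len(iu[0]):])

    v = d[:, None, None] * ta[None] + np.diag(se2)[None]
    vinv = np.linalg.inv(v)
    a = np.einsum("k,kab->ab", xtil ** 2, vinv)
    ainv = np.linalg.inv(a)
    b = np.einsum("k,kab,kb->a", xtil, vinv, ytil)
    beta = ainv @ b
    r = ytil - xtil[:, None] * beta[None, :]
    sig_g = d[:, None, None] * ta[None]                       # (n, t, t)
    w = np.einsum("kab,kbc->kac", sig_g, vinv)                # Sg V^-1
    ghat_rot = np.einsum("kab,kb->ka", w, r)
    ghat = u @ ghat_rot
    # PEV including fixed-effect uncertainty: C_kk = P_k + x_k^2 W_k A^-1 W_k'
    p_k = sig_g - np.einsum("kab,kbc->kac", w, sig_g)
    waw = np.einsum("kab,bc,kdc->kad", w, ainv, w)
    c_kk = p_k + (xtil ** 2)[:, None, None] * waw
    pev = np.einsum("nk,kaa->na", u ** 2, c_kk)
    # Cullis terms: mean diag and full sum of C_gg per trait
    sum_w = np.einsum("k,kab->ab", xtil ** 2, w)
    cross = sum_w @ ainv @ sum_w.T
    diag_sum = np.einsum("kaa->a", c_kk)
    s_full = (np.einsum("k,kaa->a", xtil ** 2, p_k)
              + np.diag(cross))
    vbar = {}
    for aix, tr in enumerate(traits):
        asum = float(diag_sum[aix])
        ssum = float(s_full[aix])
        vbar[tr] = 2.0 * (n * asum - ssum) / (n * (n - 1))

    site = "(intercept)"
    fixed = pd.DataFrame([{"trait": tr, "site": site, "estimate": beta[i]}
                          for i, tr in enumerate(traits)])
    return dict(fixed=fixed, ta=ta, se2=se2, blups=ghat, pev=pev, vbar=vbar,
                loglik=-0.5 * res.fun, n_iter=int(res.nit), trace=[],
                converged=bool(res.success or res.fun < 1e11),
                method="eigen-nm")


# ---------------------------------------------------------------------------


def fit_gblup(table: PhenotypeTable, G: RelationshipMatrix,
              traits: list[str] | None = None, tol: float = 1e-6,
              max_iter: int = 1000) -> MultiTraitFit:
    """REML fit of the (multi)trait GBLUP with fixed site effects.

    ``traits`` defaults to all traits present. The single-trait model is the
    t = 1 special case of the same machinery.
    """
    if not table.aggregated:
        table = aggregate_phenotypes(table)
    if traits is None:
        traits = sorted(table.records["trait"].unique())
    traits = list(traits)
    _check_g(G)
    rec, gsub, genos = _prepare(table, G, traits)

    # fast path: a single site and exactly one complete record per
    # genotype x trait -> the likelihood factorizes in the eigenbasis of G
    single_site = rec["site"].nunique() == 1
    counts = rec.groupby(["genotype_id", "trait"]).size()
    complete = (len(counts) == len(genos) * len(traits)
                and (counts == 1).all())
    if single_site and complete:
        wide = rec.pivot(index="genotype_id", columns="trait", values="value")
        wide = wide.loc[genos, traits]
        out = _fit_eigen(wide.to_numpy(), gsub, traits, genos)
    else:
        out = _fit_em(rec, gsub, traits, genos, tol, max_iter)

    return MultiTraitFit(
        traits=traits,
        genotype_ids=genos,
        fixed_effects=out["fixed"],
        Ta=pd.DataFrame(out["ta"], index=traits, columns=traits),
        residual_var=pd.Series(out["se2"], index=traits),
        blups=pd.DataFrame(out["blups"], index=genos, columns=traits),
        pev=pd.DataFrame(out["pev"], index=genos, columns=traits),
        cullis_vbar=pd.Series(out["vbar"]),
        loglik=float(out["loglik"]),
        converged=out["converged"],
        n_iter=out["n_iter"],
        method=out["method"],
        loglik_trace=out["trace"],
    )
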