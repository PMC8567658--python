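"""Fibre-type mediation and hormone-covariate analyses.

Fibre-type proportions are a downstream effect of sex, not a confounder, so
they cannot be added to the sex model directly.  Instead each cohort is split
by sex, methylation is regressed on the type-I fibre proportion within each
single-sex group, the groups are combined by the same inverse-variance
meta-analysis as the main analysis, and the FDR adjustment is restricted to
the previously identified sex-DMPs.

Hormone scans regress methylation on a circulating hormone (or the first
principal components of a hormone panel) within one sex; because hormones
strongly track sex, mixed-sex scans would be confounded by construction.

Also here: the free-androgen index, the Sodergard mass-action model for free
testosterone, the MYH-based fibre-type estimate from RNA-seq TPMs, and a
maximum-likelihood beta regression for proportions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .calibrate_meta import (bh_adjust, correct_scores, estimate_empirical_null,
                             ivw_meta, t_to_z)
from .core_io import CohortStudy, ValidationError
from .ewas import build_design, fit_cpg_models, ebayes_moderate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fibre-type estimation
# ---------------------------------------------------------------------------

def estimate_fibre_from_tpm(myh7, myh2, myh1):
    """Type-I fibre proportion proxy: MYH7 / (MYH7 + MYH2 + MYH1).

    MYH7 marks type I (slow), MYH2 type IIa, MYH1 type IIx fibres.  All TPMs
    must be non-negative; a zero total yields NaN with a warning.
    """
    myh7 = np.asarray(myh7, dtype=float)
    myh2 = np.asarray(myh2, dtype=float)
    myh1 = np.asarray(myh1, dtype=float)
    if (myh7 < 0).any() or (myh2 < 0).any() or (myh1 < 0).any():
        raise ValidationError("TPM values must be >= 0")
    total = myh7 + myh2 + myh1
    zero = total == 0
    if np.any(zero):
        logger.warning("%d samples with zero total MYH TPM -> NaN ratio",
                       int(np.sum(zero)))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(zero, np.nan, myh7 / np.where(zero, 1.0, total))
    return ratio if ratio.ndim else float(ratio)


# ---------------------------------------------------------------------------
# beta regression (logit mean link, constant precision)
# ---------------------------------------------------------------------------

def smithson_verkuilen(y: np.ndarray) -> np.ndarray:
    """Shrink boundary proportions into (0,1): y' = (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def beta_regression(y, X: pd.DataFrame | np.ndarray,
                    max_iter: int = 500) -> pd.DataFrame:
    """Maximum-likelihood beta regression with logit(mu) = X b, log(phi) const.

    *X* must include an intercept column (use :func:`musclemeth.ewas.build_design`).
    Boundary values of *y* are shrunk by the Smithson-Verkuilen transform.
    Returns one row per coefficient (plus ``log_phi``) with Wald z tests from
    the inverse observed information.  Raises on non-convergence with the
    gradient norm in the message.
    """
    names = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(np.shape(X)[1])]
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        y = smithson_verkuilen(y)
    n, p = Xv.shape

    def unpack(theta):
        return theta[:p], np.exp(np.clip(theta[p], -20.0, 25.0))

    ylogit = np.log(y) - np.log1p(-y)
    log_y, log_1my = np.log(y), np.log1p(-y)

    def nll(theta):
        b, phi = unpack(theta)
        mu = np.clip(special.expit(Xv @ b), 1e-10, 1 - 1e-10)
        return -np.sum(stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi))

    def grad(theta):
        # analytic score: d ll / d beta = X' [phi (y* - mu*) mu (1-mu)],
        # y* = logit(y), mu* = digamma(mu phi) - digamma((1-mu) phi)
        b, phi = unpack(theta)
        mu = np.clip(special.expit(Xv @ b), 1e-10, 1 - 1e-10)
        mu_star = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
        dbeta = Xv.T @ (phi * (ylogit - mu_star) * mu * (1.0 - mu))
        dphi = np.sum(special.digamma(phi)
                      - mu * special.digamma(mu * phi)
                      - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
                      + mu * log_y + (1.0 - mu) * log_1my)
        return -np.concatenate([dbeta, [dphi * phi]])  # d/d log(phi)

    # start: logit-scale OLS for the mean, method-of-moments precision
    ylog = np.log(y / (1.0 - y))
    b0, *_ = np.linalg.lstsq(Xv, ylog, rcond=None)
    mu0 = np.clip(special.expit(Xv @ b0), 1e-6, 1 - 1e-6)
    resid_var = max(np.var(y - mu0), 1e-6)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
    theta0 = np.concatenate([b0, [np.log(phi0)]])
    res = optimize.minimize(nll, theta0, jac=grad, method="BFGS",
                            options={"maxiter": max_iter, "gtol": 1e-8})
    if not res.success:
        polish = optimize.minimize(nll, res.x, jac=grad, method="L-BFGS-B",
                                   options={"maxiter": max_iter})
        if polish.fun <= res.fun:
            res = polish
        # steep surfaces (very large phi) defeat absolute gradient tests:
        # judge convergence by the scaled score instead
        score_scale = np.linalg.norm(grad(res.x)) / (abs(res.fun) + 1.0)
        if score_scale > 1e-3:
            raise ValidationError(
                f"beta regression did not converge (scaled gradient {score_scale:.3g})")
    # observed information via central finite differences of the analytic score
    theta = res.x
    eps = 1e-5
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        H[:, i] = (grad(tp) - grad(tm)) / (2 * eps)
    H = 0.5 * (H + H.T)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    coef = theta
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    out = pd.DataFrame({
        "term": names + ["log_phi"],
        "coef": coef,
        "se": se,
        "z": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })
    out.attrs["loglik"] = -float(res.fun)
    out.attrs["converged"] = bool(res.success or np.linalg.norm(res.jac) <= 1e-2)
    return out


def fibre_sex_difference(type1_ratio, sex, covariates: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Beta regression of the type-I fibre proportion on sex (+ covariates)."""
    df = pd.DataFrame({"sex": pd.Series(sex).astype(str),
                       "type1": np.asarray(type1_ratio, dtype=float)})
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    terms = ["sex"] + ([c for c in covariates.columns] if covariates is not None else [])
    X = build_design(df, terms)
    return beta_regression(df["type1"].to_numpy(), X)


# ---------------------------------------------------------------------------
# stratified fibre-type meta-analysis
# ---------------------------------------------------------------------------

def _fibre_group_ewas(study: CohortStudy, fibre_col: str,
                      covariates: list[str]) -> pd.DataFrame:
    """Single-sex EWAS of methylation on fibre proportion."""
    terms = [fibre_col] + [t for t in covariates if t != "sex"]
    fit = fit_cpg_models(study, terms, coef=fibre_col)
    fit = ebayes_moderate(fit)
    fit["z"] = t_to_z(fit["t_mod"].to_numpy(), fit["df_total"].to_numpy())
    null = estimate_empirical_null(fit.loc[~fit["zero_var"], "z"].to_numpy())
    return correct_scores(fit, null)


def stratified_fibre_meta(cohorts: list[CohortStudy], sex_dmps,
                          fibre_col: str = "type1_ratio",
                          covariates: dict[str, list] | None = None,
                          alpha: float = 0.005, min_samples: int = 10,
                          min_cohorts: int = 2) -> dict:
    """Sex-stratified meta-analysis of methylation on fibre-type proportion.

    Each cohort is split by sex (sex is never a regressor - it is held fixed
    by the stratification); groups with fewer than *min_samples* samples are
    excluded with a warning.  Group results are combined by IVW meta-analysis
    and BH adjustment is restricted to the supplied sex-DMP set.

    Returns a dict with the restricted meta frame, the fibre-associated CpG
    set at fdr < alpha, and the fraction of sex-DMPs they represent.
    """
    covariates = covariates or {}
    groups: dict[str, pd.DataFrame] = {}
    for study in cohorts:
        for sex in ("F", "M"):
            ids = study.samples.index[study.samples["sex"] == sex]
            if len(ids) < min_samples:
                logger.warning("group %s/%s has %d (<%d) samples; excluded",
                               study.name, sex, len(ids), min_samples)
                continue
            sub = study.subset_samples(ids)
            cov = covariates.get(study.name, [t for t in study.design_formula
                                              if "sex" not in t])
            groups[f"{study.name}_{sex}"] = _fibre_group_ewas(sub, fibre_col, cov)
    if len(groups) < 2:
        raise ValidationError("need >= 2 sex-stratified groups with fibre estimates")
    meta = ivw_meta(groups, min_cohorts=min_cohorts)
    sex_dmps = pd.Index(sex_dmps)
    restricted = meta[meta.index.isin(sex_dmps)].copy()
    restricted["fdr"] = bh_adjust(restricted["p"].to_numpy(),
                                  restricted["probe_id"].to_numpy())
    fibre_cpgs = restricted.index[restricted["fdr"] < alpha]
    return {
        "meta": meta,
        "restricted": restricted,
        "fibre_cpgs": set(fibre_cpgs),
        "n_sex_dmps_tested": len(restricted),
        "fraction_of_sex_dmps": (len(fibre_cpgs) / len(restricted)
                                 if len(restricted) else np.nan),
        "groups": list(groups),
    }


# ---------------------------------------------------------------------------
# hormone scans
# ---------------------------------------------------------------------------

def hormone_pcs(panel: pd.DataFrame, n_pcs: int = 2) -> pd.DataFrame:
    """First principal components of a standardized log-hormone panel."""
    from sklearn.decomposition import PCA

    X = np.log(panel.to_numpy(dtype=float))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X)
    return pd.DataFrame(pcs, index=panel.index,
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])


def hormone_scan(study: CohortStudy, hormone: pd.Series, sex: str,
                 covariates: list[str] | None = None, alpha: float = 0.005,
                 sex_dmps=None) -> dict:
    """EWAS of methylation on one hormone within a single sex.

    The model is DNAm ~ hormone + cohort covariates on the single-sex subset
    (a constant hormone is an error).  Reports DMP counts at fdr < alpha
    genome-wide and, when *sex_dmps* is given, within that subset with its
    own BH adjustment.
    """
    ids = study.samples.index[study.samples["sex"] == sex]
    sub = study.subset_samples(ids)
    h = hormone.reindex(sub.samples.index)
    if h.isna().any():
        h = h.fillna(h.mean())  # within-sex mean imputation, flagged
        logger.warning("imputed missing hormone values by within-sex mean")
    if float(h.std()) == 0.0:
        raise ValidationError("hormone is constant within the selected sex")
    sub.samples = sub.samples.assign(hormone=h.to_numpy(dtype=float))
    terms = ["hormone"] + [t for t in (covariates or []) if "sex" not in t]
    fit = fit_cpg_models(sub, terms, coef="hormone")
    fit = ebayes_moderate(fit)
    fit["z"] = t_to_z(fit["t_mod"].to_numpy(), fit["df_total"].to_numpy())
    null = estimate_empirical_null(fit.loc[~fit["zero_var"], "z"].to_numpy())
    fit = correct_scores(fit, null)
    fit["fdr"] = bh_adjust(fit["p_cal"].to_numpy(), fit["probe_id"].to_numpy())
    result = {"results": fit, "n_dmps": int((fit["fdr"] < alpha).sum()),
              "null": null, "sex": sex, "n": sub.n_samples}
    if sex_dmps is not None:
        sub_fit = fit[fit.index.isin(pd.Index(sex_dmps))].copy()
        sub_fit["fdr"] = bh_adjust(sub_fit["p_cal"].to_numpy(),
                                   sub_fit["probe_id"].to_numpy())
        result["n_dmps_in_sex_dmps"] = int((sub_fit["fdr"] < alpha).sum())
    return result


# ---------------------------------------------------------------------------
# hormone-derived indices
# ---------------------------------------------------------------------------

#: association constants (L/mol) and default albumin, standard literature values
K_SHBG = 1.0e9
K_ALBUMIN = 3.6e4
ALBUMIN_G_PER_DL = 4.3
ALBUMIN_MOLAR_MASS = 66_430.0  # g/mol


def albumin_molar(albumin_g_dl: float = ALBUMIN_G_PER_DL) -> float:
    return albumin_g_dl * 10.0 / ALBUMIN_MOLAR_MASS  # g/dL -> g/L -> mol/L


def free_testosterone(total_t_nmol, shbg_nmol, albumin_g_dl: float = ALBUMIN_G_PER_DL,
                      k_shbg: float = K_SHBG, k_alb: float = K_ALBUMIN):
    """Free testosterone (pmol/L) from the mass-action binding equilibrium.

    Total T is partitioned between the free pool and saturable binding to
    SHBG and albumin: T = F + S*Ks*F/(1+Ks*F) + A*Ka*F/(1+Ka*F), a cubic in
    the free concentration F with a unique positive root.
    """
    T = np.asarray(total_t_nmol, dtype=float) * 1e-9   # mol/L
    S = np.asarray(shbg_nmol, dtype=float) * 1e-9
    A = albumin_molar(albumin_g_dl)
    if (T <= 0).any() or (S <= 0).any():
        raise ValidationError("total T and SHBG must be > 0")
    out = np.empty(T.shape if T.ndim else (1,))
    Tf, Sf = np.atleast_1d(T), np.atleast_1d(S)
    for i in range(out.size):
        t, s = Tf[i], Sf[i]
        # cubic coefficients from clearing denominators of the balance
        a3 = k_shbg * k_alb
        a2 = k_shbg + k_alb + k_shbg * k_alb * (s + A - t)
        a1 = 1.0 + k_shbg * (s - t) + k_alb * (A - t)
        a0 = -t
        roots = np.roots([a3, a2, a1, a0])
        scale = max(np.abs(roots).max(), 1e-30)
        pos = roots[(np.abs(roots.imag) < 1e-8 * scale) & (roots.real > 0)].real
        if pos.size == 0:
            raise ValidationError("no positive root in free-testosterone cubic")
        out[i] = pos.min() * 1e12  # mol/L -> pmol/L
    return out if T.ndim else float(out[0])


def free_testosterone_fixed_point(total_t_nmol: float, shbg_nmol: float,
                                  albumin_g_dl: float = ALBUMIN_G_PER_DL,
                                  k_shbg: float = K_SHBG, k_alb: float = K_ALBUMIN,
                                  tol: float = 1e-10, max_iter: int = 10_000) -> float:
    """Independent fixed-point solver of the same binding equations (oracle)."""
    t = total_t_nmol * 1e-9
    s = shbg_nmol * 1e-9
    A = albumin_molar(albumin_g_dl)
    f = t / 2.0
    for _ in range(max_iter):
        f_new = t / (1.0 + k_shbg * s / (1.0 + k_shbg * f) + k_alb * A / (1.0 + k_alb * f))
        if abs(f_new - f) < tol * max(f, 1e-30):
            f = f_new
            break
        f = f_new
    return f * 1e12


def derive_hormone_indices(panel: pd.DataFrame,
                           albumin_g_dl: float = ALBUMIN_G_PER_DL) -> pd.DataFrame:
    """Add FAI = T*100/SHBG and Sodergard free testosterone to a panel.

    Requires columns ``T`` (nmol/L) and ``SHBG`` (nmol/L); free testosterone
    is returned in pmol/L.
    """
    for col in ("T", "SHBG"):
        if col not in panel.columns:
            raise ValidationError(f"hormone panel missing column {col!r}")
        if (panel[col] <= 0).any():
            raise ValidationError(f"{col} must be > 0 for hormone indices")
    out = panel.copy()
    out["FAI"] = out["T"] * 100.0 / out["SHBG"]
    out["free_T"] = free_testosterone(out["T"].to_numpy(), out["SHBG"].to_numpy(),
                                      albumin_g_dl)
    return out
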