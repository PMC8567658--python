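"""Per-cohort EWAS: probe-wise linear models with empirical-Bayes moderation.

Each CpG is regressed on sex plus cohort-specific covariates by ordinary
least squares, vectorised across probes.  Residual variances are then shrunk
toward a common prior by the standard empirical-Bayes scheme (moments of log
sample variances matched to a scaled-F prior), yielding moderated t
statistics with ``df_total = d0 + df_resid``.

Sex is coded F = 0, M = 1, so a positive effect means hypermethylated in
males.  Effects are mean beta-value differences (proportion units; multiply
by 100 for the % scale used in reporting).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import CohortStudy, ValidationError

logger = logging.getLogger(__name__)

SEX_CODE = {"F": 0.0, "M": 1.0}


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _expand_terms(terms: list[str]) -> list[str]:
    """Expand 'a*b' into main effects + interaction, preserving order."""
    out: list[str] = []
    for term in terms:
        if "*" in term:
            a, b = (t.strip() for t in term.split("*", 1))
            for t in (a, b, f"{a}:{b}"):
                if t not in out:
                    out.append(t)
        elif term not in out:
            out.append(term.strip())
    return out


def _encode(samples: pd.DataFrame, col: str) -> pd.DataFrame:
    """Numeric column -> itself; categorical -> treatment-coded dummies."""
    if col == "sex":
        return pd.DataFrame({"sex": samples["sex"].map(SEX_CODE).astype(float)})
    s = samples[col]
    if pd.api.types.is_numeric_dtype(s):
        return pd.DataFrame({col: s.astype(float)})
    levels = sorted(s.astype(str).unique())
    return pd.DataFrame(
        {f"{col}[{lv}]": (s.astype(str) == lv).astype(float) for lv in levels[1:]},
        index=s.index)


def build_design(samples: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Build an intercept-first design frame from declared model terms.

    Supports main effects, ``a:b`` interactions and ``a*b`` expansion.
    Categorical covariates are treatment-coded against their first
    (lexicographic) level.  Raises on a rank-deficient design, naming the
    aliased columns.
    """
    cols = {"Intercept": pd.Series(1.0, index=samples.index)}
    for term in _expand_terms(terms):
        if ":" in term:
            a, b = term.split(":", 1)
            da, db = _encode(samples, a), _encode(samples, b)
            for ca in da.columns:
                for cb in db.columns:
                    cols[f"{ca}:{cb}"] = da[ca] * db[cb]
        else:
            for c, v in _encode(samples, term).items():
                cols[c] = v
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        keep: list[int] = []
        M = X.to_numpy()
        for j in range(M.shape[1]):
            if np.linalg.matrix_rank(M[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                aliased.append(X.columns[j])
        raise ValidationError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return X


def impute_covariates(samples: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Impute missing numeric covariates by the within-sex mean (flagged)."""
    out = samples.copy()
    for col in columns:
        if out[col].isna().any():
            n = int(out[col].isna().sum())
            out[col] = out[col].fillna(out.groupby("sex")[col].transform("mean"))
            out[f"{col}_imputed"] = samples[col].isna()
            logger.info("imputed %d missing values in %r by within-sex mean", n, col)
    return out


# ---------------------------------------------------------------------------
# repeated measures
# ---------------------------------------------------------------------------

def collapse_repeats(study: CohortStudy, condition_cols: list[str] | None = None
                     ) -> CohortStudy:
    """Average repeated samples within each subject x condition cell.

    This is a deliberate simplification of consensus-correlation blocking: it
    keeps sex effects unbiased while reducing each subject to one observation
    per condition.  Categorical covariates must be constant within a cell;
    numeric covariates are averaged.  Conflicting sex within a subject is an
    error.
    """
    cols = ["subject_id"] + list(condition_cols or [])
    samples = study.samples
    if samples.groupby("subject_id")["sex"].nunique().gt(1).any():
        bad = samples.groupby("subject_id")["sex"].nunique()
        raise ValidationError(
            f"conflicting sex within subject(s): {list(bad[bad > 1].index)}")
    key = samples[cols].astype(str).agg("|".join, axis=1)
    if key.is_unique:
        return study  # no repeats
    groups = samples.groupby(key, sort=True)
    new_beta = {}
    new_rows = []
    for gkey, idx in groups.groups.items():
        ids = list(idx)
        new_id = gkey.replace("|", "_")
        new_beta[new_id] = study.beta[ids].mean(axis=1)
        row = samples.loc[ids[0]].copy()
        for c in samples.columns:
            if pd.api.types.is_numeric_dtype(samples[c]):
                row[c] = samples.loc[ids, c].mean()
        row["n_collapsed"] = len(ids)
        row.name = new_id
        new_rows.append(row)
    beta = pd.DataFrame(new_beta, index=study.beta.index)
    new_samples = pd.DataFrame(new_rows)
    new_samples.index.name = "sample_id"
    return CohortStudy(study.name, beta, new_samples, list(study.design_formula),
                       study.unannotated)


# ---------------------------------------------------------------------------
# probe-wise OLS
# ---------------------------------------------------------------------------

def fit_cpg_models(study: CohortStudy, terms: list[str] | None = None,
                   coef: str = "sex") -> pd.DataFrame:
    """Fit per-probe OLS models and extract one coefficient (default sex).

    Returns a frame with columns ``probe_id, effect, se, t, p, df_resid,
    sigma2, stdev_unscaled, n, zero_var``.  Zero-variance probes are flagged
    and get p = 1; they are excluded from moderation downstream.
    """
    terms = list(terms) if terms is not None else list(study.design_formula)
    X = build_design(study.samples, terms)
    if coef not in X.columns:
        raise ValidationError(f"coefficient {coef!r} not in design columns {list(X.columns)}")
    Xv = X.to_numpy()
    n, p = Xv.shape
    df_resid = n - p
    if df_resid < 2:
        raise ValidationError(f"residual df {df_resid} < 2 (n={n}, p={p})")
    Y = study.beta.to_numpy()
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    B = Y @ Xv @ XtX_inv.T                      # probes x p
    resid = Y - B @ Xv.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df_resid
    j = list(X.columns).index(coef)
    v = XtX_inv[j, j]
    effect = B[:, j]
    zero_var = sigma2 <= 1e-30
    se = np.sqrt(np.where(zero_var, np.nan, sigma2) * v)
    with np.errstate(invalid="ignore"):
        t = effect / se
    pval = 2.0 * stats.t.sf(np.abs(t), df_resid)
    pval = np.where(zero_var, 1.0, pval)
    return pd.DataFrame({
        "probe_id": study.beta.index,
        "effect": effect,
        "se": se,
        "t": t,
        "p": pval,
        "df_resid": float(df_resid),
        "sigma2": sigma2,
        "stdev_unscaled": np.sqrt(v),
        "n": n,
        "zero_var": zero_var,
    }).set_index("probe_id", drop=False)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_f_dist(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from sample
    variances by matching moments of log variances to a scaled-F model.

    Returns ``(d0, s02)``; ``d0`` may be ``inf`` when variances are
    effectively homogeneous.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
    ok = np.isfinite(sigma2) & (sigma2 > 0)
    if not ok.all():
        raise ValidationError("non-finite or non-positive variances passed to fit_f_dist")
    z = np.log(sigma2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # observed log-variances under-dispersed relative to pure sampling
        # noise: infinite prior df; shrink to the geometric mean variance so
        # identical sample variances are a fixed point of the moderation
        d0 = np.inf
        s02 = float(np.exp(z.mean()))
    return float(d0), s02


def ebayes_moderate(fit: pd.DataFrame, min_probes: int = 100) -> pd.DataFrame:
    """Shrink per-probe variances and compute moderated t statistics.

    Posterior variance ``s2_post = (d0*s0^2 + df*s^2) / (d0 + df)``;
    ``t_mod = effect / (s_post * stdev_unscaled)``; two-sided p from a t
    distribution on ``d0 + df`` df.  Zero-variance probes are excluded from
    hyperparameter estimation and keep p = 1.
    """
    ok = ~fit["zero_var"].to_numpy()
    if ok.sum() < min_probes:
        raise ValidationError(
            f"need >= {min_probes} probes with positive variance for moderation")
    d0, s02 = fit_f_dist(fit.loc[ok, "sigma2"].to_numpy(),
                         fit.loc[ok, "df_resid"].to_numpy())
    out = fit.copy()
    df = out["df_resid"].to_numpy()
    s2 = out["sigma2"].to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = out["effect"].to_numpy() / (np.sqrt(s2_post) * out["stdev_unscaled"].to_numpy())
    p = np.where(np.isinf(df_total),
                 2.0 * stats.norm.sf(np.abs(t_mod)),
                 2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)))
    zero = out["zero_var"].to_numpy()
    out["s2_post"] = s2_post
    out["t_mod"] = np.where(zero, 0.0, t_mod)
    out["df_total"] = df_total
    out["p"] = np.where(zero, 1.0, p)
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    return out


def run_ewas(study: CohortStudy, terms: list[str] | None = None,
             collapse: bool = True, condition_cols: list[str] | None = None,
             coef: str = "sex") -> pd.DataFrame:
    """Convenience wrapper: collapse repeats, fit per-CpG models, moderate."""
    if collapse:
        study = collapse_repeats(study, condition_cols)
    fit = fit_cpg_models(study, terms, coef=coef)
    return ebayes_moderate(fit)


# ---------------------------------------------------------------------------
# cohort characteristics
# ---------------------------------------------------------------------------

def cohort_characteristics(samples: pd.DataFrame,
                           continuous: list[str] = ("age",),
                           categorical: list[str] = ()) -> pd.DataFrame:
    """Male-female comparisons of cohort covariates.

    Welch two-sample t-test for continuous covariates; two-sided Fisher's
    exact test for binary categorical covariates (2x2 sex-by-level table).
    Covariates with an empty group are reported as NA.
    """
    male = samples[samples["sex"] == "M"]
    female = samples[samples["sex"] == "F"]
    rows = []
    for col in continuous:
        x, y = male[col].dropna(), female[col].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append({"covariate": col, "test": "welch_t", "stat": np.nan, "p": np.nan})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"covariate": col, "test": "welch_t", "stat": float(t), "p": float(p)})
    for col in categorical:
        levels = sorted(samples[col].dropna().astype(str).unique())
        if len(levels) != 2 or len(male) == 0 or len(female) == 0:
            rows.append({"covariate": col, "test": "fisher_exact", "stat": np.nan, "p": np.nan})
            continue
        table = [[int((female[col].astype(str) == lv).sum()),
                  int((male[col].astype(str) == lv).sum())] for lv in levels]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"covariate": col, "test": "fisher_exact", "stat": float(odds), "p": float(p)})
    return pd.DataFrame(rows)
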