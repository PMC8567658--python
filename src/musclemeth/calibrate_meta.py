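"""Empirical-null calibration, fixed-effects meta-analysis and DMP calling.

Per-cohort test statistics are first re-expressed as z-scores, then the bias
``mu`` and inflation ``sigma`` of the empirical null are estimated with a
three-component Gaussian mixture (one null, one positive-signal and one
negative-signal component) fitted by constrained EM with deterministic
initialisation.  Calibrated scores ``z' = (z - mu) / sigma`` feed an
inverse-variance-weighted fixed-effects meta-analysis with Cochran's Q and
I-squared heterogeneity, followed by Benjamini-Hochberg FDR and DMP calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError

logger = logging.getLogger(__name__)

#: median chi-square(1), denominator of the genomic inflation factor
CHI2_MEDIAN = 0.4549364231195724


def lambda_gc(z: np.ndarray) -> float:
    """Genomic inflation factor: median(z^2) / median(chi2_1)."""
    z = np.asarray(z, dtype=float)
    return float(np.median(z ** 2) / CHI2_MEDIAN)


def t_to_z(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Map t statistics to standard-normal scores preserving sign and tail p."""
    t = np.asarray(t, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    logp = stats.t.logsf(np.abs(t), df)  # one-sided log tail, stable far out
    z_abs = stats.norm.isf(np.exp(np.maximum(logp, -700.0)))
    deep = logp < -700.0  # beyond double underflow: asymptotic tail inversion
    if np.any(deep):
        lp = logp[deep]
        z_abs[deep] = np.sqrt(-2.0 * lp - np.log(-2.0 * lp) - np.log(2.0 * np.pi))
    return np.sign(t) * z_abs


# ---------------------------------------------------------------------------
# empirical null (bias/inflation) estimation
# ---------------------------------------------------------------------------

@dataclass
class NullEstimate:
    """Empirical-null parameters of an EWAS z-score vector.

    mu : bias of the null component (z units).
    sigma : inflation (dimensionless, > 0).
    p0 : estimated null proportion.
    lambda_gc : genomic inflation factor of the raw scores.
    converged : whether EM reached the log-likelihood tolerance.
    """

    mu: float
    sigma: float
    p0: float
    lambda_gc: float
    converged: bool = True
    n_iter: int = 0


def estimate_empirical_null(z: np.ndarray, tol: float = 1e-6,
                            max_iter: int = 1000) -> NullEstimate:
    """Fit a three-Gaussian mixture to z-scores and return the null component.

    Deterministic initialisation: null mean = median(z), null sd =
    1.4826 * MAD, signal components at +/- 3 sd with weight 0.1 each
    (p0 = 0.8).  Component means are kept ordered (mu- < mu < mu+) with the
    signal components constrained away from the null (see inline comment).
    On non-convergence the (median, MAD) estimator is returned with a warning.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10_000:
        logger.warning("empirical-null estimation on %d scores (<10k recommended)", z.size)
    med = float(np.median(z))
    mad_sd = float(np.median(np.abs(z - med))) * 1.4826
    if mad_sd <= 0:
        mad_sd = float(np.std(z)) or 1.0
    lam = lambda_gc(z)

    mu = np.array([med, med + 3.0 * mad_sd, med - 3.0 * mad_sd])
    sd = np.array([mad_sd, mad_sd, mad_sd])
    w = np.array([0.8, 0.1, 0.1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        dens = np.stack([wk * stats.norm.pdf(z, m, s)
                         for wk, m, s in zip(w, mu, sd)])
        tot = dens.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        resp = dens / tot
        ll = float(np.log(tot).sum())
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / z.size
        mu = (resp @ z) / nk
        sd = np.sqrt(np.maximum((resp @ (z ** 2)) / nk - mu ** 2, 1e-6))
        # separation constraints: signal components must stay >= 2 null-sd
        # from the null mean and be at least 1.25x as wide as the null,
        # otherwise they absorb null tail mass and deflate the inflation
        # estimate (the null component must own the centre of the mixture)
        mu[1] = max(mu[1], mu[0] + 2.0 * sd[0])
        mu[2] = min(mu[2], mu[0] - 2.0 * sd[0])
        sd[1:] = np.maximum(sd[1:], 1.25 * sd[0])
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    if not converged or not (0 < w[0] <= 1) or not np.isfinite(mu[0] + sd[0]):
        logger.warning("empirical-null EM did not converge; falling back to median/MAD")
        return NullEstimate(med, mad_sd, 1.0, lam, converged=False, n_iter=it)
    return NullEstimate(float(mu[0]), float(sd[0]), float(w[0]), lam,
                        converged=True, n_iter=it)


def correct_scores(ewas: pd.DataFrame, null: NullEstimate) -> pd.DataFrame:
    """Apply bias/inflation correction to an EWAS result frame.

    Requires a ``z`` column (see :func:`t_to_z`); adds ``z_cal``, ``p_cal``
    and ``se_cal`` (= effect / z_cal, preserving effect-size units so the
    meta-analysis weights reflect the calibrated precision).  Effects are
    unchanged.  ``z_cal == 0`` yields infinite se (zero weight).
    """
    out = ewas.copy()
    z = out["z"].to_numpy(dtype=float)
    z_cal = (z - null.mu) / null.sigma
    p_cal = 2.0 * stats.norm.sf(np.abs(z_cal))
    with np.errstate(divide="ignore", invalid="ignore"):
        se_cal = out["effect"].to_numpy() / z_cal
    se_cal = np.abs(se_cal)
    se_cal[z_cal == 0] = np.inf
    out["z_cal"] = z_cal
    out["p_cal"] = p_cal
    out["se_cal"] = se_cal
    return out


# ---------------------------------------------------------------------------
# inverse-variance-weighted fixed-effects meta-analysis
# ---------------------------------------------------------------------------

def ivw_meta(results: dict[str, pd.DataFrame], min_cohorts: int = 2,
             effect_col: str = "effect", se_col: str = "se_cal") -> pd.DataFrame:
    """Combine per-cohort results with inverse-variance weights.

    Each value of *results* must be indexed by probe_id and carry effect and
    se columns.  Probes present in fewer than *min_cohorts* cohorts are
    dropped, as are cohort entries with non-finite or zero weight.  Returns a
    frame with combined ``effect, se, z, p, q_stat, q_p, i2, k, direction``.
    """
    names = list(results)
    all_probes = pd.Index(sorted(set().union(*(df.index for df in results.values()))))
    k_total = len(names)
    b = np.full((len(all_probes), k_total), np.nan)
    s = np.full((len(all_probes), k_total), np.nan)
    for j, name in enumerate(names):
        df = results[name]
        loc = all_probes.get_indexer(df.index)
        b[loc, j] = df[effect_col].to_numpy(dtype=float)
        s[loc, j] = df[se_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / s ** 2
    w[~np.isfinite(w)] = 0.0
    w[~np.isfinite(b)] = 0.0
    valid = w > 0
    k = valid.sum(axis=1)
    keep = k >= min_cohorts
    if (~keep).any():
        logger.info("dropping %d probes present in < %d cohorts", int((~keep).sum()),
                    min_cohorts)
    b0 = np.where(valid, b, 0.0)
    sw = w.sum(axis=1)
    effect = (w * b0).sum(axis=1) / np.where(sw > 0, sw, np.nan)
    se = 1.0 / np.sqrt(np.where(sw > 0, sw, np.nan))
    z = effect / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = (w * (b0 - effect[:, None]) ** 2).sum(axis=1)
    dfq = np.maximum(k - 1, 1)
    q_p = stats.chi2.sf(q, dfq)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.maximum(0.0, (q - (k - 1)) / np.where(q > 0, q, np.nan)) * 100.0
    i2 = np.where(np.isnan(i2), 0.0, i2)
    signs = np.where(valid, np.sign(b0), np.nan)
    direction = ["".join("?" if np.isnan(x) else ("+" if x > 0 else ("-" if x < 0 else "0"))
                         for x in row) for row in signs]
    out = pd.DataFrame({
        "probe_id": all_probes,
        "effect": effect, "se": se, "z": z, "p": p,
        "q_stat": q, "q_p": q_p, "i2": i2, "k": k,
        "direction": direction,
    }).set_index("probe_id", drop=False)
    out = out[keep]
    out.attrs["cohorts"] = names
    return out


# ---------------------------------------------------------------------------
# FDR and DMP calling
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray, ids=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Ties are handled by a stable sort on (p, id) so results are reproducible
    regardless of input order.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids, dtype=object), p))
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def call_dmps(meta: pd.DataFrame, alpha: float = 0.005) -> tuple[pd.DataFrame, dict]:
    """BH-adjust meta p-values and call DMPs at fdr < alpha.

    Returns the frame with added ``fdr`` and ``is_dmp`` columns and a summary
    dict with DMP counts and hyper/hypo fractions (hyper = positive effect =
    higher methylation in males).
    """
    out = meta.copy()
    out["fdr"] = bh_adjust(out["p"].to_numpy(), out["probe_id"].to_numpy())
    out["is_dmp"] = out["fdr"] < alpha
    dmps = out[out["is_dmp"]]
    n = len(dmps)
    n_hyper = int((dmps["effect"] > 0).sum())
    n_hypo = int((dmps["effect"] < 0).sum())
    summary = {
        "n_tested": len(out),
        "n_dmps": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "frac_hypo": n_hypo / n if n else np.nan,
        "mean_delta_hyper_pct": float(dmps.loc[dmps["effect"] > 0, "effect"].mean() * 100) if n_hyper else np.nan,
        "mean_delta_hypo_pct": float(dmps.loc[dmps["effect"] < 0, "effect"].mean() * 100) if n_hypo else np.nan,
    }
    return out, summary


# ---------------------------------------------------------------------------
# PCA variance explained by sex
# ---------------------------------------------------------------------------

def pca_variance_explained(beta_dmps: pd.DataFrame, sex: pd.Series,
                           n_pcs: int = 5) -> tuple[int, float]:
    """How much of the leading variation at the DMPs is explained by sex.

    PCA of the samples x DMPs matrix (probes centred and scaled); the chosen
    PC is the one among the first *n_pcs* with the largest absolute
    point-biserial correlation with sex; its adjusted R^2 from the OLS
    ``PC ~ sex`` is returned along with the (0-based) PC index.
    """
    from sklearn.decomposition import PCA

    if beta_dmps.shape[0] < 2:
        raise ValidationError("need >= 2 probes for PCA")
    sx = sex.map({"F": 0.0, "M": 1.0}) if sex.dtype == object else sex.astype(float)
    if sx.nunique() < 2 or min((sx == 0).sum(), (sx == 1).sum()) < 2:
        raise ValidationError("need >= 2 samples per sex")
    X = beta_dmps.to_numpy().T  # samples x probes
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X)
    s = sx.to_numpy()
    r = np.array([np.corrcoef(pcs[:, i], s)[0, 1] for i in range(n_pcs)])
    best = int(np.argmax(np.abs(r)))
    n = len(s)
    r2 = r[best] ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return best, float(adj_r2)
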