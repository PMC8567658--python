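"""Genomic-context, TFBS and gene-set enrichment for DMPs.

Three families of tests:

* contingency tests of DMP status against genomic categories (chromatin
  states, CpG-island relation) with standardized Pearson residuals flagging
  the cells that drive the association;
* a 2x2 odds-ratio test for DMPs falling in chromatin states that differ
  between male and female reference muscle;
* probe-bias-aware gene-set tests: genes covered by many probes are more
  likely to contain a significant probe by chance, so the null draws genes
  with probability proportional to their probe count (Wallenius noncentral
  hypergeometric, or a Monte-Carlo sampler that is exact in the limit).

TFBS enrichment is a one-sided Fisher test per interval dataset against the
tested-CpG background, reported unadjusted (datasets are not independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError, cpgs_in_intervals


@dataclass
class ContingencyResult:
    """Counts, chi-square / Fisher statistics and residual diagnostics."""

    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    pearson_residuals: pd.DataFrame   # (O-E)/sqrt(E); squares sum to chi2
    std_residuals: pd.DataFrame       # adjusted residuals, ~N(0,1) cellwise
    flagged: pd.DataFrame | None = None  # |std residual| above threshold
    odds_ratio: float | None = None   # 2x2 only
    or_ci: tuple | None = None
    fisher_p: float | None = None
    warnings: list = field(default_factory=list)


def _chi2_decompose(table: pd.DataFrame) -> ContingencyResult:
    obs = table.to_numpy(dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    pearson = (obs - expected) / np.sqrt(expected)
    adj = pearson / np.sqrt((1.0 - row / n) * (1.0 - col / n))
    return ContingencyResult(
        table=table, chi2=chi2, df=df, p=p,
        pearson_residuals=pd.DataFrame(pearson, index=table.index, columns=table.columns),
        std_residuals=pd.DataFrame(adj, index=table.index, columns=table.columns),
    )


def context_chi2(status: pd.Series, category: pd.Series,
                 residual_threshold: float = 4.0) -> ContingencyResult:
    """Chi-square homogeneity test of DMP status against a genomic category.

    *status* partitions probes (e.g. hyper / hypo / non); *category* is the
    genomic label (chromatin state, island relation).  Cells whose adjusted
    standardized residual exceeds *residual_threshold* in absolute value are
    flagged as driving the association.  Expected counts below 5 in more than
    20% of cells trigger a warning (and a Fisher fallback p for 2x2 tables).
    """
    aligned = pd.DataFrame({"status": status, "category": category}).dropna()
    table = pd.crosstab(aligned["status"], aligned["category"])
    if table.to_numpy().sum() == 0:
        raise ValidationError("empty contingency table")
    res = _chi2_decompose(table)
    expected = (table.sum(1).to_numpy()[:, None] @ table.sum(0).to_numpy()[None, :]
                / table.to_numpy().sum())
    if (expected < 5).mean() > 0.2:
        res.warnings.append("more than 20% of cells have expected count < 5")
        if table.shape == (2, 2):
            res.fisher_p = float(stats.fisher_exact(table.to_numpy())[1])
    res.flagged = res.std_residuals.abs() > residual_threshold
    return res


def sex_state_or(dmp_flag: pd.Series, discordant_flag: pd.Series) -> ContingencyResult:
    """Odds of a DMP lying in a sex-discordant chromatin state.

    2x2 Fisher exact test; the odds ratio is oriented as (non-DMP odds of a
    discordant state) / (DMP odds of a discordant state), so values below 1
    mean DMPs are *over*-represented in discordant states.  The 95% CI uses
    the Woolf logit method (Haldane-Anscombe 0.5 correction on zero cells,
    CI only).
    """
    aligned = pd.DataFrame({"dmp": dmp_flag.astype(bool),
                            "disc": discordant_flag.astype(bool)}).dropna()
    # rows: non-DMP, DMP; cols: discordant, concordant
    a = int((~aligned["dmp"] & aligned["disc"]).sum())
    b = int((~aligned["dmp"] & ~aligned["disc"]).sum())
    c = int((aligned["dmp"] & aligned["disc"]).sum())
    d = int((aligned["dmp"] & ~aligned["disc"]).sum())
    table = pd.DataFrame([[a, b], [c, d]], index=["non_dmp", "dmp"],
                         columns=["discordant", "concordant"])
    return contingency_2x2(table)


def contingency_2x2(table: pd.DataFrame) -> ContingencyResult:
    """Fisher exact + cross-product OR with Woolf logit 95% CI for a 2x2."""
    (a, b), (c, d) = table.to_numpy(dtype=float)
    res = _chi2_decompose(table)
    res.odds_ratio = (a * d) / (b * c) if b * c > 0 else np.inf
    aa, bb, cc, dd = ((x + 0.5 if min(a, b, c, d) == 0 else x) for x in (a, b, c, d))
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    res.or_ci = (float(np.exp(log_or - 1.959963985 * se)),
                 float(np.exp(log_or + 1.959963985 * se)))
    res.fisher_p = float(stats.fisher_exact(table.to_numpy().astype(int))[1])
    return res


# ---------------------------------------------------------------------------
# probe-bias-corrected gene-set testing
# ---------------------------------------------------------------------------

def _probe_counts(probe_genes: pd.Series, probes) -> pd.Series:
    """Number of probes per gene over a probe universe (a probe annotated to
    several genes contributes to each of them)."""
    counts: dict[str, int] = {}
    for pid in probes:
        for g in probe_genes.get(pid, []):
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=float)


def gene_set_test(sig_probes, background_probes, probe_genes: pd.Series,
                  gene_sets: dict[str, list], method: str = "montecarlo",
                  n_iter: int = 10_000, rng=None) -> pd.DataFrame:
    """Test gene sets for enrichment among differentially methylated genes.

    Significant genes are genes with >= 1 significant probe.  The null
    accounts for probe-number bias: genes with more probes are more likely to
    be called.  ``wallenius`` uses the noncentral hypergeometric tail with
    odds = (mean probe count of set genes) / (mean probe count of non-set
    genes); ``montecarlo`` draws gene sets of the observed size with
    probability proportional to probe count, ``p = (1 + #{overlap >= obs}) /
    (n_iter + 1)``.

    Returns one row per set: ``set, N`` (set genes present on the array),
    ``DE`` (significant genes in the set), ``p``, ``sig_genes``.
    """
    if len(background_probes) == 0:
        raise ValidationError("empty background probe set")
    rng = np.random.default_rng(rng)
    counts = _probe_counts(probe_genes, background_probes)
    universe = counts.index
    sig_genes_all = set()
    for pid in sig_probes:
        sig_genes_all.update(probe_genes.get(pid, []))
    sig_genes_all &= set(universe)
    k_sig = len(sig_genes_all)
    sig_mask = universe.isin(sig_genes_all)
    weights = counts.to_numpy()
    rows = []
    for name, genes in gene_sets.items():
        in_set = universe.isin([g.upper() for g in genes] + list(genes))
        n_set = int(in_set.sum())
        if n_set == 0:
            rows.append({"set": name, "N": 0, "DE": 0, "p": 1.0, "sig_genes": []})
            continue
        observed = int((in_set & sig_mask).sum())
        if method == "wallenius":
            odds = (weights[in_set].mean() / weights[~in_set].mean()
                    if (~in_set).sum() else 1.0)
            dist = stats.nchypergeom_wallenius(len(universe), n_set, k_sig, odds)
            p = float(dist.sf(observed - 1))
        elif method == "montecarlo":
            if k_sig == 0:
                p = 1.0
            else:
                ge = 0
                set_idx = np.flatnonzero(in_set)
                logw = np.log(weights)
                chunk = max(1, min(n_iter, int(4e6 / max(len(universe), 1))))
                done = 0
                while done < n_iter:
                    m = min(chunk, n_iter - done)
                    gumbel = rng.gumbel(size=(m, len(universe)))
                    keys = logw[None, :] + gumbel
                    top = np.argpartition(keys, -k_sig, axis=1)[:, -k_sig:]
                    ge += int((np.isin(top, set_idx).sum(axis=1) >= observed).sum())
                    done += m
                p = (1.0 + ge) / (n_iter + 1.0)
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append({"set": name, "N": n_set, "DE": observed, "p": p,
                     "sig_genes": sorted(set(universe[in_set & sig_mask]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TFBS enrichment
# ---------------------------------------------------------------------------

def tfbs_enrichment(dmp_probes, tfbs_beds: dict[str, pd.DataFrame],
                    annotation: pd.DataFrame,
                    background_probes=None) -> pd.DataFrame:
    """One-sided Fisher enrichment of DMPs in each TFBS interval dataset.

    The background is the full set of tested CpGs (DMPs excluded from the
    comparison column).  Overlap follows the half-open BED convention: a CpG
    at 1-based position p hits [s, e) iff s <= p - 1 < e.  Datasets with zero
    overlapping probes get p = 1 and a flag.  Results are unadjusted and
    ranked by -log10 p.
    """
    if background_probes is None:
        background_probes = annotation["probe_id"]
    bg = pd.Index(background_probes)
    ann = annotation[annotation["probe_id"].isin(bg)]
    dmp = pd.Index(dmp_probes).intersection(bg)
    non = bg.difference(dmp)
    rows = []
    for name, bed in tfbs_beds.items():
        hits = cpgs_in_intervals(ann, bed)
        in_tf = set(hits.index[hits])
        a = len([p for p in dmp if p in in_tf])       # DMP in TFBS
        b = len(dmp) - a
        c = len([p for p in non if p in in_tf])       # non-DMP in TFBS
        d = len(non) - c
        if a + c == 0:
            rows.append({"dataset": name, "dmp_in": 0, "bg_in": 0,
                         "odds_ratio": np.nan, "p": 1.0, "no_overlap": True})
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"dataset": name, "dmp_in": a, "bg_in": c,
                     "odds_ratio": float(odds), "p": float(p), "no_overlap": False})
    out = pd.DataFrame(rows)
    out["neg_log10_p"] = -np.log10(np.clip(out["p"], 1e-300, 1.0))
    return out.sort_values("neg_log10_p", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# overlap resampling against an external CpG list
# ---------------------------------------------------------------------------

def overlap_resampling(dmps, reference, universe, n_iter: int = 10_000,
                       rng=None) -> tuple[float, int]:
    """Resampling p for the overlap of DMPs with an external CpG set.

    Draws |reference| probes uniformly from *universe* n_iter times and
    counts how often the overlap with the DMP set reaches the observed one;
    p = (1 + #{null >= observed}) / (n_iter + 1).
    """
    rng = np.random.default_rng(rng)
    universe = pd.Index(universe)
    reference = pd.Index(reference)
    if not reference.isin(universe).all():
        raise ValidationError("reference CpGs must be a subset of the universe")
    dmps = pd.Index(dmps)
    observed = int(len(reference.intersection(dmps)))
    dmp_mask = universe.isin(dmps).astype(np.int64)
    n_u, k = len(universe), len(reference)
    ge = 0
    for _ in range(n_iter):
        draw = rng.choice(n_u, size=k, replace=False)
        if dmp_mask[draw].sum() >= observed:
            ge += 1
    return (1.0 + ge) / (n_iter + 1.0), observed
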