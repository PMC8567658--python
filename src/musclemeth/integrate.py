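"""Methylation-expression integration and qPCR validation.

* Venn-style overlap of differentially methylated genes (DMGs) with one or
  more differential-expression gene lists, with a probe-bias-aware
  enrichment p (the DEG list is treated as a gene set).
* Quadrant concordance: how often the methylation effect of a promoter- or
  enhancer-annotated DMR has the opposite sign to the expression effect of
  its gene, with a permutation null that shuffles methylation effects within
  each region class.
* Relative qPCR quantification by 2^-ddCt with housekeeper normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError


def harmonize_genes(genes) -> list[str]:
    """Uppercase gene symbols, drop empties; order preserved, unique."""
    seen, out = set(), []
    for g in genes:
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        u = str(g).strip().upper()
        if u and u not in seen:
            seen.add(u)
            out.append(u)
    return out


def dmg_deg_overlap(dmgs, deg_lists: dict[str, list],
                    probe_genes: pd.Series | None = None,
                    background_probes=None, sig_probes=None,
                    rng=None, n_iter: int = 10_000) -> dict:
    """Venn counts of DMGs against expression gene lists, plus enrichment.

    Returns a dict with per-list intersection counts, all Venn cells over
    (DMG, first two DEG lists), and - when the probe universe is supplied -
    the bias-adjusted enrichment p of each DEG list among the DMGs via
    :func:`musclemeth.enrichment.gene_set_test`.
    """
    dmg = set(harmonize_genes(dmgs))
    lists = {name: set(harmonize_genes(g)) for name, g in deg_lists.items()}
    out: dict = {"n_dmgs": len(dmg)}
    for name, genes in lists.items():
        out[f"n_{name}"] = len(genes)
        out[f"dmg_and_{name}"] = len(dmg & genes)
    names = list(lists)
    if len(names) >= 2:
        a, b = lists[names[0]], lists[names[1]]
        out["venn"] = {
            "dmg_only": len(dmg - a - b),
            f"{names[0]}_only": len(a - dmg - b),
            f"{names[1]}_only": len(b - dmg - a),
            f"dmg_{names[0]}": len((dmg & a) - b),
            f"dmg_{names[1]}": len((dmg & b) - a),
            f"{names[0]}_{names[1]}": len((a & b) - dmg),
            "all_three": len(dmg & a & b),
        }
    if probe_genes is not None and background_probes is not None and sig_probes is not None:
        from .enrichment import gene_set_test
        res = gene_set_test(sig_probes, background_probes, probe_genes,
                            {name: sorted(g) for name, g in lists.items()},
                            method="montecarlo", n_iter=n_iter, rng=rng)
        out["enrichment"] = res
    return out


@dataclass
class QuadrantResult:
    """Inverse-correlation fractions by region class with permutation p."""

    n_pairs: dict
    inverse_fraction: dict
    p: dict
    n_iter: int
    seed: int | None = None


def quadrant_concordance(pairs: pd.DataFrame, n_iter: int = 10_000,
                         seed=None, classes=("promoter", "enhancer")) -> QuadrantResult:
    """Permutation test for inverse methylation-expression correlation.

    *pairs* has one row per DMR-gene pair with columns ``meth_effect``,
    ``expr_effect`` and ``region_class``.  Pairs with a zero effect on either
    axis are dropped (count logged in the result).  Within each region class
    the methylation effect vector is permuted across pairs; the p-value is
    the fraction of permutations whose inverse fraction reaches the observed
    one, with the (1 + b) / (1 + n) estimator.
    """
    rng = np.random.default_rng(seed)
    n_pairs, frac, pvals = {}, {}, {}
    for cls in classes:
        sub = pairs[pairs["region_class"] == cls]
        m = sub["meth_effect"].to_numpy(dtype=float)
        e = sub["expr_effect"].to_numpy(dtype=float)
        nz = (np.sign(m) != 0) & (np.sign(e) != 0)
        m, e = m[nz], e[nz]
        n_pairs[cls] = int(nz.sum())
        if m.size == 0:
            frac[cls] = np.nan
            pvals[cls] = 1.0
            continue
        sm, se_ = np.sign(m), np.sign(e)
        observed = float((sm != se_).mean())
        frac[cls] = observed
        ge = 0
        for _ in range(n_iter):
            perm = rng.permutation(sm)
            if (perm != se_).mean() >= observed:
                ge += 1
        pvals[cls] = (1.0 + ge) / (n_iter + 1.0)
    return QuadrantResult(n_pairs=n_pairs, inverse_fraction=frac, p=pvals,
                          n_iter=n_iter, seed=seed)


def pair_dmrs_with_expression(dmrs: pd.DataFrame, annotation: pd.DataFrame,
                              expression: pd.DataFrame) -> pd.DataFrame:
    """Build DMR-gene pairs for the quadrant analysis.

    A DMR is assigned to the promoter class when any member CpG lies in a
    promoter-type chromatin state (TssA/TssAFlnk) and to the enhancer class
    when any member lies in an enhancer-type state (Enh/EnhG); a region can
    contribute to both classes.  Each of the region's genes with an
    expression effect yields one pair per class, so a gene with several DMRs
    in one class contributes one pair per DMR.
    """
    reg = annotation.set_index("probe_id")["regulatory_class"]
    expr = expression.copy()
    expr["gene"] = harmonize_genes_series(expr["gene"])
    expr = expr.drop_duplicates("gene").set_index("gene")["effect"]
    rows = []
    for _, r in dmrs.iterrows():
        classes = set(reg.reindex([p for p in r["probes"] if p in reg.index])
                      .dropna()) & {"promoter", "enhancer"}
        for cls in sorted(classes):
            for g in r.get("genes", []):
                gu = str(g).upper()
                if gu in expr.index:
                    rows.append({"meth_effect": r["meandiff"],
                                 "expr_effect": expr[gu],
                                 "region_class": cls, "gene": gu})
    return pd.DataFrame(rows, columns=["meth_effect", "expr_effect",
                                       "region_class", "gene"])


def harmonize_genes_series(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.upper()


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def select_housekeepers(ct: pd.DataFrame, candidates: list[str],
                        n_select: int = 2) -> list[str]:
    """Pick the most stable housekeepers: lowest variance of per-sample mean
    Ct across samples."""
    means = (ct[ct["gene"].isin(candidates)]
             .groupby(["gene", "sample"])["Ct"].mean().unstack("sample"))
    stability = means.var(axis=1).sort_values()
    return list(stability.index[:n_select])


def qpcr_fold_change(ct: pd.DataFrame, housekeepers: list[str],
                     groups: pd.Series, sd_max: float = 1.0) -> pd.DataFrame:
    """Relative expression by 2^-ddCt with housekeeper normalisation.

    *ct* is long-format (sample, gene, replicate, Ct).  Triplicates with Ct
    standard deviation above *sd_max* are excluded.  dCt = Ct_target - mean
    of the housekeeper Cts (geometric-mean normalisation on the expression
    scale); per-sample expression is 2^-dCt; the fold change is the ratio of
    male to female mean expression (2^-ddCt) with a two-sided Welch t-test on
    dCt.
    """
    missing = [h for h in housekeepers if h not in set(ct["gene"])]
    if missing:
        raise ValidationError(f"missing housekeeper gene(s): {missing}")
    stats_ct = ct.groupby(["sample", "gene"])["Ct"].agg(["mean", "std", "count"])
    ok = (stats_ct["std"].fillna(0.0) <= sd_max)
    mean_ct = stats_ct.loc[ok, "mean"].unstack("gene")
    hk = mean_ct[housekeepers].mean(axis=1)  # arithmetic mean of Ct = geometric mean scale
    rows = []
    targets = [g for g in mean_ct.columns if g not in housekeepers]
    for gene in targets:
        dct = (mean_ct[gene] - hk).dropna()
        grp = groups.reindex(dct.index)
        m = dct[grp == "M"]
        f = dct[grp == "F"]
        if len(m) == 0 or len(f) == 0:
            rows.append({"gene": gene, "fold_change": np.nan, "p": np.nan,
                         "n_m": len(m), "n_f": len(f)})
            continue
        ddct = m.mean() - f.mean()
        fc = float(2.0 ** (-ddct))
        if len(m) > 1 and len(f) > 1:
            p = float(stats.ttest_ind(m, f, equal_var=False)[1])
        else:
            p = np.nan
        rows.append({"gene": gene, "fold_change": fc, "p": p,
                     "n_m": len(m), "n_f": len(f)})
    return pd.DataFrame(rows)
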