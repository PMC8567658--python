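"""Kernel-smoothing DMR caller with Stouffer / Fisher / HMFDR region statistics.

Per-CpG squared meta z-scores (chi-square(1) under the null) are smoothed
along each chromosome with a Gaussian kernel of bandwidth sigma = lambda / C
(defaults lambda = 1000 bp, C = 2), truncated at 3 sigma for linear-time
scanning.  The null of the smoothed statistic is approximated by
Satterthwaite moment matching: with normalised weights w~, Y = sum(w~ z^2)
is treated as c * chi2(nu) with scale c = sum(w~^2) and df nu = 1 / c.
Significant CpGs (BH fdr on the smoothed p) within lambda of each other are
merged into regions; regions need at least ``min_cpgs`` members and carry
three combined statistics (all must fall below the cutoff for significance):

* stouffer - normal combination of member signed z derived from member FDR;
* fisher_p - Fisher's chi-square(2k) combination of member meta p-values;
* hmfdr    - harmonic mean of member FDR values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError


def _smooth_chrom(pos: np.ndarray, z2: np.ndarray, sigma: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-Gaussian smoothing of z^2 along one sorted chromosome.

    Returns (smoothed statistic Y, scale c of the Satterthwaite null).
    """
    n = pos.size
    y = np.empty(n)
    c = np.empty(n)
    cut = 3.0 * sigma
    lo = np.searchsorted(pos, pos - cut, side="left")
    hi = np.searchsorted(pos, pos + cut, side="right")
    for i in range(n):
        d = pos[lo[i]:hi[i]] - pos[i]
        w = np.exp(-d.astype(float) ** 2 / (2.0 * sigma ** 2))
        w /= w.sum()
        y[i] = float(w @ z2[lo[i]:hi[i]])
        c[i] = float(w @ w)
    return y, c


def smooth_statistics(meta: pd.DataFrame, lambda_: float = 1000.0,
                      C: float = 2.0) -> pd.DataFrame:
    """Add smoothed per-CpG statistics and p-values to an annotated meta frame.

    *meta* must carry ``chrom``, ``pos`` and ``z`` columns.  An isolated CpG
    (no neighbour within 3 sigma) keeps its own chi-square(1) tail p.
    """
    for col in ("chrom", "pos", "z"):
        if col not in meta.columns:
            raise ValidationError(f"smooth_statistics requires column {col!r}")
    sigma = lambda_ / C
    out = meta.sort_values(["chrom", "pos"], kind="stable").copy()
    y_all = np.empty(len(out))
    c_all = np.empty(len(out))
    start = 0
    for _, grp in out.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        z2 = grp["z"].to_numpy(dtype=float) ** 2
        y, c = _smooth_chrom(pos, z2, sigma)
        y_all[start:start + len(grp)] = y
        c_all[start:start + len(grp)] = c
        start += len(grp)
    nu = 1.0 / c_all
    out["smooth_stat"] = y_all
    out["smooth_df"] = nu
    out["smooth_p"] = stats.chi2.sf(y_all / c_all, nu)
    return out


def call_regions(smoothed: pd.DataFrame, lambda_: float = 1000.0,
                 alpha: float = 0.005, min_cpgs: int = 2,
                 fdr_col: str = "fdr", p_col: str = "p") -> pd.DataFrame:
    """Group significant smoothed CpGs into DMRs and score them.

    *smoothed* is the output of :func:`smooth_statistics` joined with the
    meta-analysis columns ``effect``, *p_col* (per-CpG meta p) and *fdr_col*
    (per-CpG BH fdr).  Smoothed p-values are BH-adjusted genome-wide;
    CpGs with smoothed fdr < *alpha* are merged into maximal runs with
    consecutive gaps <= *lambda_*; runs with >= *min_cpgs* members become
    regions.  Returns one row per region with combined statistics, effect
    summaries (``maxdiff`` keeps the sign of the largest |delta-beta|) and
    the member probe ids.
    """
    from .calibrate_meta import bh_adjust

    df = smoothed.sort_values(["chrom", "pos"], kind="stable").copy()
    df["smooth_fdr"] = bh_adjust(df["smooth_p"].to_numpy(),
                                 df["probe_id"].to_numpy())
    sig = df[df["smooth_fdr"] < alpha]
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > lambda_)
        bounds = np.concatenate(([0], breaks + 1, [len(grp)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            run = grp.iloc[a:b]
            if len(run) < min_cpgs:
                continue
            k = len(run)
            eff = run["effect"].to_numpy(dtype=float)
            p = np.clip(run[p_col].to_numpy(dtype=float), 1e-300, 1.0)
            fdr = np.clip(run[fdr_col].to_numpy(dtype=float), 1e-300, 1.0)
            # Stouffer on signed z from member FDR (one-sided mapping)
            z_mem = np.sign(eff) * stats.norm.isf(np.clip(fdr / 2.0, 1e-300, 0.999999))
            z_bar = z_mem.sum() / np.sqrt(k)
            stouffer = 2.0 * stats.norm.sf(abs(z_bar))
            fisher_p = float(stats.chi2.sf(-2.0 * np.log(p).sum(), 2 * k))
            hmfdr = float(k / np.sum(1.0 / fdr))
            imax = int(np.argmax(np.abs(eff)))
            regions.append({
                "chrom": chrom,
                "start": int(run["pos"].iloc[0]),
                "end": int(run["pos"].iloc[-1]),
                "n_cpgs": k,
                "stouffer": float(stouffer),
                "fisher_p": fisher_p,
                "hmfdr": hmfdr,
                "maxdiff": float(eff[imax]),
                "meandiff": float(eff.mean()),
                "probes": list(run["probe_id"]),
            })
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_cpgs",
                                         "stouffer", "fisher_p", "hmfdr",
                                         "maxdiff", "meandiff", "probes"])
    if len(out):
        out["significant"] = ((out["stouffer"] < alpha) & (out["fisher_p"] < alpha)
                              & (out["hmfdr"] < alpha))
        out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def map_dmrs_to_genes(dmrs: pd.DataFrame, annotation: pd.DataFrame
                      ) -> tuple[set, pd.DataFrame]:
    """Annotate regions to genes via the union of member-CpG gene lists.

    Returns the unique differentially-methylated-gene set and a per-gene DMR
    count frame.  Intergenic regions contribute an empty list but are kept.
    """
    gene_lists = annotation.set_index("probe_id")["genes"]
    counts: dict[str, int] = {}
    genes_col = []
    for probes in dmrs["probes"]:
        region_genes: set = set()
        for pid in probes:
            if pid in gene_lists.index:
                region_genes.update(gene_lists.loc[pid])
        genes_col.append(sorted(region_genes))
        for g in region_genes:
            counts[g] = counts.get(g, 0) + 1
    dmrs = dmrs.copy()
    dmrs["genes"] = genes_col
    all_genes = set(counts)
    per_gene = (pd.DataFrame({"gene": list(counts), "n_dmrs": list(counts.values())})
                .sort_values("gene").reset_index(drop=True))
    per_gene.attrs["dmrs"] = dmrs
    return all_genes, per_gene


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """BED-like TSV export (0-based start, end inclusive position)."""
    out = dmrs.copy()
    out["start0"] = out["start"] - 1
    out["name"] = [f"dmr_{i}" for i in range(len(out))]
    out["genes"] = out.get("genes", pd.Series([[]] * len(out))).map(";".join)
    cols = ["chrom", "start0", "end", "name", "n_cpgs", "stouffer",
            "fisher_p", "hmfdr", "maxdiff", "meandiff", "genes"]
    out[cols].to_csv(path, sep="\t", index=False)
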