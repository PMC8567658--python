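"""End-to-end orchestration of the sex-differential methylation analysis.

``run_sex_meta`` chains the per-cohort EWAS (with empirical-Bayes variance
moderation), per-cohort bias/inflation calibration against the empirical
null, probe intersection (>= 2 cohorts), fixed-effects IVW meta-analysis,
BH FDR / DMP calling and - when annotation is supplied - kernel-smoothed DMR
calling with gene mapping.
"""

from __future__ import annotations

import logging

import pandas as pd

from .calibrate_meta import (call_dmps, correct_scores, estimate_empirical_null,
                             ivw_meta, t_to_z)
from .core_io import CohortStudy, intersect_probes
from .dmr import call_regions, map_dmrs_to_genes, smooth_statistics
from .ewas import run_ewas

logger = logging.getLogger(__name__)


def run_sex_meta(studies: list[CohortStudy], annotation: pd.DataFrame | None = None,
                 alpha: float = 0.005, min_cohorts: int = 2,
                 collapse: bool = True, condition_cols: list[str] | None = None,
                 call_dmrs: bool = True, dmr_lambda: float = 1000.0) -> dict:
    """Run the full inference chain and return all intermediate products.

    Returns a dict with ``ewas`` (per-cohort calibrated results), ``nulls``
    (per-cohort empirical-null estimates), ``meta`` (combined frame with fdr
    and is_dmp), ``summary`` (DMP counts / hyper-hypo split), and, with
    annotation, ``dmrs`` and ``dmgs``.
    """
    meta_probes, membership = intersect_probes(studies, min_cohorts)
    ewas_results: dict[str, pd.DataFrame] = {}
    nulls = {}
    for study in studies:
        res = run_ewas(study, collapse=collapse, condition_cols=condition_cols)
        res["z"] = t_to_z(res["t_mod"].to_numpy(), res["df_total"].to_numpy())
        null = estimate_empirical_null(res.loc[~res["zero_var"], "z"].to_numpy())
        nulls[study.name] = null
        ewas_results[study.name] = correct_scores(res, null)
        logger.info("%s: lambda_gc=%.3f bias=%.3f inflation=%.3f", study.name,
                    null.lambda_gc, null.mu, null.sigma)
    meta = ivw_meta(ewas_results, min_cohorts=min_cohorts)
    meta = meta[meta.index.isin(meta_probes)]
    meta, summary = call_dmps(meta, alpha=alpha)
    out = {"ewas": ewas_results, "nulls": nulls, "meta": meta,
           "summary": summary, "membership": membership}
    if annotation is not None and call_dmrs:
        coords = annotation.set_index("probe_id")[["chrom", "pos"]]
        annotated = meta.join(coords, how="inner")
        smoothed = smooth_statistics(annotated, lambda_=dmr_lambda)
        dmrs = call_regions(smoothed, lambda_=dmr_lambda, alpha=alpha)
        sig = dmrs[dmrs["significant"]] if len(dmrs) else dmrs
        genes, per_gene = map_dmrs_to_genes(sig, annotation)
        out["dmrs"] = dmrs
        out["significant_dmrs"] = per_gene.attrs["dmrs"]  # sig regions + genes
        out["dmgs"] = genes
        out["dmg_counts"] = per_gene
    return out
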