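"""Synthetic multi-cohort methylation studies with planted ground truth.

The generator produces 2-4 cohorts of beta values on a shared synthetic probe
set with the statistical structure the downstream analysis assumes:

* probes laid out in correlated clusters along a synthetic autosomal genome
  (clusters double as plantable differentially methylated regions);
* sex effects that are predominantly one-directional (by default 94% of
  affected probes are hypomethylated in males, with mean |delta-beta| 0.035
  for hypo- and 0.028 for hyper-methylated probes);
* fibre-type-mediated effects driven by a per-sample type-I fibre proportion
  drawn from sex-specific Beta distributions (females higher on average);
* batch/chip offsets, subject random intercepts and repeated measures;
* one optional small-array cohort carrying only 1/20 of the probes, which
  exercises the "present in >= 2 cohorts" meta rule.

Signal is composed on the logit2 (M-value) scale and mapped back to [0, 1];
planted effect sizes are specified as the delta-beta they would produce at a
baseline beta of 0.5 and recovery is always evaluated on the delta-beta
scale.  Everything is driven by one mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (CHROMATIN_STATES, ISLAND_RELATIONS, AUTOSOMES,
                      CohortStudy, ValidationError, beta_to_m, m_to_beta,
                      write_annotation, write_beta_matrix)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Effect-size defaults mirror the magnitudes the analysis is meant to
    detect: 94% of sex-affected probes hypomethylated in males, mean
    |delta-beta| of 0.028 (hyper) and 0.035 (hypo).  Fibre-type proportions
    are Beta-distributed with female mean 0.52 and male mean 0.42 at
    precision 30, a detectable but realistic mediator.
    """

    n_cohorts: int = 3
    n_probes: int = 20_000
    n_samples: tuple = (100, 60, 24)          # per cohort, split evenly by sex
    frac_sex_cpgs: float = 0.10
    frac_hypo_in_males: float = 0.94
    effect_mean_hyper: float = 0.028          # mean |delta-beta|, hyper in males
    effect_mean_hypo: float = 0.035           # mean |delta-beta|, hypo in males
    effect_size: float | None = None          # fixed |delta-beta| override
    frac_fibre_cpgs: float = 0.015            # fibre-responsive probes
    fibre_effect: float = 0.15                # delta-beta per unit type-I proportion
    frac_sex_cpgs_fibre_mediated: float = 0.0 # planted sex CpGs that are also fibre CpGs
    fibre_beta_mean_f: float = 0.52
    fibre_beta_mean_m: float = 0.42
    fibre_beta_precision: float = 30.0
    batch_sd: float = 0.05                    # logit2 units
    subject_sd: float = 0.10                  # logit2 units
    residual_sd: float = 0.25                 # logit2 units
    block_bp: int = 1_000                     # correlation length (cluster span)
    block_size: int = 8                       # probes per cluster
    block_rho: float = 0.5                    # shared-noise fraction within cluster
    n_batches: int = 2
    repeated_measures: bool = False           # duplicate each subject (2 timepoints)
    small_array_cohort: bool = True           # last cohort carries 1/20 of probes
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        for name in ("frac_sex_cpgs", "frac_hypo_in_males", "frac_fibre_cpgs",
                     "frac_sex_cpgs_fibre_mediated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 2 <= self.n_cohorts <= 4:
            raise ValidationError("n_cohorts must be in 2..4")
        if len(self.n_samples) < self.n_cohorts:
            raise ValidationError("n_samples must list one size per cohort")


def _delta_m(delta_beta: np.ndarray) -> np.ndarray:
    """logit2-scale effect that yields *delta_beta* at baseline beta 0.5."""
    half = np.clip(np.abs(delta_beta) / 2.0, 0.0, 0.499999)
    return np.sign(delta_beta) * (beta_to_m(0.5 + half) - beta_to_m(0.5 - half))


def _synthetic_annotation(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe map: clusters of `block_size` probes spanning <= block_bp, with
    inter-cluster gaps far beyond the DMR merging distance."""
    n = cfg.n_probes
    block = max(cfg.block_size, 1)
    n_blocks = int(np.ceil(n / block))
    chroms = np.array(AUTOSOMES)[rng.integers(0, 22, size=n_blocks)]
    # deterministic per-chromosome layout: blocks placed sequentially
    order = np.argsort(chroms, kind="stable")
    pos = np.empty(n, dtype=int)
    chrom_col = np.empty(n, dtype=object)
    block_id = np.empty(n, dtype=int)
    cursor: dict[str, int] = {}
    i = 0
    for b in order:
        c = chroms[b]
        start = cursor.get(c, 10_000) + 10 * cfg.block_bp  # >> 3*sigma apart
        size = min(block, n - i)
        within = np.sort(rng.choice(np.arange(cfg.block_bp), size=size, replace=False))
        pos[i:i + size] = start + within
        chrom_col[i:i + size] = c
        block_id[i:i + size] = b
        cursor[c] = int(pos[i + size - 1])
        i += size
        if i >= n:
            break
    genes = np.array([f"G{b:05d}" for b in block_id], dtype=object)
    island = rng.choice(ISLAND_RELATIONS, size=n, p=[0.3, 0.25, 0.1, 0.35])
    state_m = rng.choice(CHROMATIN_STATES, size=n)
    discord = rng.random(n) < 0.33
    state_f = state_m.copy()
    alt = rng.choice(CHROMATIN_STATES, size=n)
    # force a different label where discordant
    state_index = {s: i for i, s in enumerate(CHROMATIN_STATES)}
    same = alt == state_m
    alt[same] = np.array(CHROMATIN_STATES)[
        [(state_index[s] + 1) % len(CHROMATIN_STATES) for s in state_m[same]]]
    state_f[discord] = alt[discord]
    ann = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(n)],
        "chrom": chrom_col,
        "pos": pos,
        "genes": [[g] for g in genes],
        "island_relation": island,
        "state_male": state_m,
        "state_female": state_f,
        "block": block_id,
    })
    from .core_io import validate_annotation
    return validate_annotation(ann)


def _plant_truth(cfg: SimConfig, ann: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Choose sex- and fibre-affected probes (whole clusters for sex effects,
    so planted signal forms contiguous regions) and their delta-beta sizes."""
    n = cfg.n_probes
    blocks = ann["block"].to_numpy()
    uniq = np.unique(blocks)
    n_sex = int(round(cfg.frac_sex_cpgs * n))
    sex_effect = np.zeros(n)
    is_sex = np.zeros(n, dtype=bool)
    if n_sex > 0:
        block_order = rng.permutation(uniq)
        chosen: list[int] = []
        count = 0
        sizes = pd.Series(np.arange(n)).groupby(blocks).size()
        for b in block_order:
            chosen.append(b)
            count += int(sizes.loc[b])
            if count >= n_sex:
                break
        idx = np.flatnonzero(np.isin(blocks, chosen))
        is_sex[idx] = True
        # one sign per cluster: predominantly hypomethylated in males
        sign_by_block = {b: (-1.0 if rng.random() < cfg.frac_hypo_in_males else 1.0)
                         for b in chosen}
        signs = np.array([sign_by_block[b] for b in blocks[idx]])
        if cfg.effect_size is not None:
            mag = np.full(idx.size, float(cfg.effect_size))
        else:
            mean = np.where(signs < 0, cfg.effect_mean_hypo, cfg.effect_mean_hyper)
            mag = rng.exponential(mean)
        sex_effect[idx] = np.clip(signs * mag, -0.5, 0.5)
    # fibre-affected probes: a planted share of sex CpGs plus background probes
    is_fibre = np.zeros(n, dtype=bool)
    fibre_effect = np.zeros(n)
    n_med = int(round(cfg.frac_sex_cpgs_fibre_mediated * is_sex.sum()))
    if n_med > 0:
        med_idx = rng.choice(np.flatnonzero(is_sex), size=n_med, replace=False)
        is_fibre[med_idx] = True
    n_bg = int(round(cfg.frac_fibre_cpgs * n))
    pool = np.flatnonzero(~is_sex)
    if n_bg > 0 and pool.size:
        bg_idx = rng.choice(pool, size=min(n_bg, pool.size), replace=False)
        is_fibre[bg_idx] = True
    fidx = np.flatnonzero(is_fibre)
    if fidx.size:
        fsigns = rng.choice([-1.0, 1.0], size=fidx.size, p=[0.3, 0.7])
        fibre_effect[fidx] = fsigns * cfg.fibre_effect
    return pd.DataFrame({
        "probe_id": ann["probe_id"].to_numpy(),
        "sex_effect": sex_effect,
        "fibre_effect": fibre_effect,
        "is_sex_cpg": is_sex,
        "is_fibre_cpg": is_fibre,
    }).set_index("probe_id", drop=False)


def _simulate_one_cohort(name: str, n_samples: int, cfg: SimConfig,
                         ann: pd.DataFrame, truth: pd.DataFrame,
                         baseline_m: np.ndarray,
                         rng: np.random.Generator) -> CohortStudy:
    probes = ann["probe_id"].to_numpy()
    n_probes = probes.size
    n_f = n_samples // 2
    n_m = n_samples - n_f
    sex = np.array(["F"] * n_f + ["M"] * n_m)
    n_subj = n_samples
    subj = np.array([f"{name}_S{i:03d}" for i in range(n_subj)])
    # per-sample fibre type-I proportion, sex-specific Beta
    phi = cfg.fibre_beta_precision
    mean = np.where(sex == "F", cfg.fibre_beta_mean_f, cfg.fibre_beta_mean_m)
    type1 = rng.beta(mean * phi, (1.0 - mean) * phi)
    batch = rng.integers(0, cfg.n_batches, size=n_subj)

    reps = 2 if cfg.repeated_measures else 1
    sample_ids, rows = [], []
    for t in range(reps):
        for i in range(n_subj):
            sid = f"{name}_S{i:03d}_T{t}" if reps > 1 else f"{name}_S{i:03d}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "subject_id": subj[i], "sex": sex[i],
                         "age": float(rng.normal(45, 10)),
                         "batch": f"b{batch[i]}",
                         "timepoint": f"t{t}",
                         "type1_ratio": float(type1[i])})
    samples = pd.DataFrame(rows).set_index("sample_id")

    sex_dm = _delta_m(truth["sex_effect"].to_numpy())
    fibre_dm = _delta_m(truth["fibre_effect"].to_numpy())
    is_m = (samples["sex"] == "M").to_numpy(dtype=float)
    t1 = samples["type1_ratio"].to_numpy()

    n_total = len(samples)
    M = np.empty((n_probes, n_total))
    # fixed effects: baseline + sex + fibre (centred so sex effect stays M-F)
    M[:] = baseline_m[:, None]
    M += sex_dm[:, None] * (is_m[None, :] - 0.5)
    M += fibre_dm[:, None] * (t1[None, :] - t1.mean())
    # batch offsets (per probe x batch)
    batch_levels = sorted(samples["batch"].unique())
    boff = rng.normal(0.0, cfg.batch_sd, size=(n_probes, len(batch_levels)))
    bidx = samples["batch"].map({b: i for i, b in enumerate(batch_levels)}).to_numpy()
    M += boff[:, bidx]
    # subject random intercepts (shared across repeats)
    soff = rng.normal(0.0, cfg.subject_sd, size=(n_probes, n_subj))
    sidx = samples["subject_id"].map({s: i for i, s in enumerate(subj)}).to_numpy()
    M += soff[:, sidx]
    # residual noise with within-cluster correlation
    rho = np.clip(cfg.block_rho, 0.0, 0.99)
    blocks = ann["block"].to_numpy()
    shared = rng.normal(0.0, cfg.residual_sd, size=(blocks.max() + 1, n_total))
    M += np.sqrt(rho) * shared[blocks]
    M += np.sqrt(1.0 - rho) * rng.normal(0.0, cfg.residual_sd, size=(n_probes, n_total))

    beta = pd.DataFrame(m_to_beta(M), index=probes, columns=samples.index)
    formula = ["sex", "age", "batch"]
    if reps > 1:
        formula = ["sex*timepoint", "age", "batch"]
    return CohortStudy(name, beta, samples, formula)


def simulate_cohorts(config: SimConfig
                     ) -> tuple[list[CohortStudy], pd.DataFrame, pd.DataFrame]:
    """Generate cohorts, probe annotation and the planted truth table.

    Identical seeds give identical output.  When ``small_array_cohort`` is
    set, the last cohort carries only every 20th probe (emulating a legacy
    small array), so those probes remain testable under the >= 2-cohort rule
    only through the remaining cohorts.
    """
    rng = np.random.default_rng(config.seed)
    ann = _synthetic_annotation(config, rng)
    truth = _plant_truth(config, ann, rng)
    # bimodal baseline on the beta scale, mapped to logit2
    comp = rng.random(config.n_probes)
    base_beta = np.where(comp < 0.45, rng.beta(2, 8, config.n_probes),
                         np.where(comp < 0.9, rng.beta(8, 2, config.n_probes),
                                  rng.beta(4, 4, config.n_probes)))
    baseline_m = beta_to_m(np.clip(base_beta, 0.03, 0.97))
    studies = []
    for c in range(config.n_cohorts):
        name = f"cohort{c + 1}"
        study = _simulate_one_cohort(name, int(config.n_samples[c]), config,
                                     ann, truth, baseline_m, rng)
        if config.small_array_cohort and c == config.n_cohorts - 1:
            keep = ann["probe_id"].to_numpy()[::20]
            study = study.subset_probes(keep)
        studies.append(study)
    return studies, ann, truth


def simulate_expression(truth: pd.DataFrame, gene_map: pd.DataFrame,
                        coupling: float, rng=None,
                        effect_sd: float = 1.0) -> pd.DataFrame:
    """Per-gene differential-expression table coupled to planted methylation.

    For each gene carrying at least one sex-affected probe, the expression
    effect sign is opposite to the gene's mean planted methylation effect
    with probability *coupling* and random otherwise.  *gene_map* maps
    probe_id -> gene (columns ``probe_id, gene``).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValidationError("coupling must be in [0, 1]")
    rng = np.random.default_rng(rng)
    merged = gene_map.merge(truth[["probe_id", "sex_effect"]].reset_index(drop=True),
                            on="probe_id")
    per_gene = merged.groupby("gene")["sex_effect"].mean()
    per_gene = per_gene[per_gene != 0]
    genes = per_gene.index.to_numpy()
    meth_sign = np.sign(per_gene.to_numpy())
    inverse = rng.random(genes.size) < coupling
    rand_sign = rng.choice([-1.0, 1.0], size=genes.size)
    expr_sign = np.where(inverse, -meth_sign, rand_sign)
    effect = expr_sign * np.abs(rng.normal(0.0, effect_sd, size=genes.size))
    return pd.DataFrame({
        "gene": genes,
        "effect": effect,
        "significance": rng.uniform(0.0, 0.004, size=genes.size),
        "meth_effect": per_gene.to_numpy(),
    })


#: default log-scale hormone means/sds by sex (units as in a serum panel)
HORMONE_PARAMS = {
    "T":            {"M": (20.0, 0.25), "F": (1.2, 0.35)},   # nmol/L
    "E2":           {"M": (100.0, 0.3), "F": (400.0, 0.5)},  # pmol/L
    "SHBG":         {"M": (40.0, 0.3),  "F": (60.0, 0.35)},  # nmol/L
    "FSH":          {"M": (4.0, 0.3),   "F": (6.0, 0.5)},    # IU/L
    "LH":           {"M": (5.0, 0.3),   "F": (7.0, 0.5)},    # IU/L
    "progesterone": {"M": (1.0, 0.3),   "F": (2.0, 0.6)},    # nmol/L
}


def simulate_hormones(samples: pd.DataFrame, rng=None,
                      params: dict = HORMONE_PARAMS) -> pd.DataFrame:
    """Log-normal hormone panel with sex-specific geometric means.

    Independent of methylation by construction, so hormone scans on these
    values are genuine nulls.
    """
    if not set(samples["sex"]) <= {"M", "F"}:
        raise ValidationError("sex labels must be M/F")
    rng = np.random.default_rng(rng)
    out = pd.DataFrame(index=samples.index)
    sex = samples["sex"]
    for hormone, by_sex in params.items():
        vals = np.empty(len(samples))
        for s in ("M", "F"):
            gm, sd = by_sex[s]
            mask = (sex == s).to_numpy()
            vals[mask] = np.exp(rng.normal(np.log(gm), sd, size=int(mask.sum())))
        out[hormone] = vals
    return out


def write_study_dir(studies: list[CohortStudy], ann: pd.DataFrame,
                    truth: pd.DataFrame, outdir) -> None:
    """Write the standard on-disk layout: per-cohort beta matrix + sample
    sheet, annotation manifest and truth table."""
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in studies:
        write_beta_matrix(s, out / f"{s.name}_beta.tsv", out / f"{s.name}_samples.tsv")
    write_annotation(ann, out / "annotation.tsv")
    truth.reset_index(drop=True).to_csv(out / "truth.tsv", sep="\t", index=False)
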