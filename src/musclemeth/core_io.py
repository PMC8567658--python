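"""Core containers, readers/writers and probe bookkeeping for methylation-array cohorts.

A cohort is a beta-value matrix (probes x samples, values in [0, 1]) plus a
sample sheet with at least ``sample_id``, ``subject_id``, ``sex`` (M/F) and
``age``.  Probe annotation is a plain :class:`pandas.DataFrame` keyed by
``probe_id`` with genomic coordinates (1-based point positions), gene lists,
CpG-island relation and male/female chromatin-state labels.

Coordinate convention: manifest positions are 1-based points; all interval
files (chromatin states, TFBS) are BED dialect, 0-based half-open.  A CpG at
1-based position ``p`` overlaps interval ``[s, e)`` iff ``s <= p - 1 < e``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: 18 chromatin-state labels (reference-epigenome style segmentation).
CHROMATIN_STATES = (
    "TssA", "TssAFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG", "Enh", "EnhA", "EnhWk", "ZNF/Rpts", "Het",
    "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

PROMOTER_STATES = frozenset({"TssA", "TssAFlnk"})
ENHANCER_STATES = frozenset({"Enh", "EnhG"})

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")

#: required columns of a probe-annotation frame
ANNOTATION_COLUMNS = (
    "probe_id", "chrom", "pos", "genes", "island_relation",
    "state_male", "state_female",
)

EPS_BETA = 1e-6  # clip bound for logit transforms


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CohortStudy:
    """One cohort: beta matrix, sample sheet and declared model terms.

    Parameters
    ----------
    name : cohort label.
    beta : DataFrame, probes x samples, values in [0, 1]; index = probe ids.
    samples : DataFrame indexed by ``sample_id`` with ``subject_id``, ``sex``
        (M/F), ``age`` and free covariate columns.
    design_formula : ordered list of model terms beyond the intercept, e.g.
        ``["sex", "age", "batch"]`` or ``["sex*timepoint", "age"]``.
    """

    name: str
    beta: pd.DataFrame
    samples: pd.DataFrame
    design_formula: list[str] = field(default_factory=lambda: ["sex"])
    unannotated: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r} in cohort {self.name}")
        if self.samples.index.name != "sample_id":
            if "sample_id" in self.samples.columns:
                self.samples = self.samples.set_index("sample_id")
            else:
                self.samples.index.name = "sample_id"
        if self.samples.index.duplicated().any():
            raise ValidationError(f"duplicate sample ids in cohort {self.name}")
        if list(self.beta.columns) != list(self.samples.index):
            missing = set(self.beta.columns) ^ set(self.samples.index)
            if missing:
                raise ValidationError(
                    f"beta columns and sample sheet disagree in {self.name}: {sorted(missing)[:5]}"
                )
            self.samples = self.samples.loc[self.beta.columns]
        vals = self.beta.to_numpy()
        bad = ~((vals >= 0.0) & (vals <= 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        bad_sex = set(self.samples["sex"].unique()) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"sex labels must be M/F, got {sorted(bad_sex)}")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probes) -> "CohortStudy":
        keep = self.beta.index.intersection(pd.Index(probes))
        return CohortStudy(self.name, self.beta.loc[keep], self.samples.copy(),
                           list(self.design_formula), self.unannotated)

    def subset_samples(self, sample_ids) -> "CohortStudy":
        ids = [s for s in sample_ids if s in self.beta.columns]
        return CohortStudy(self.name, self.beta[ids], self.samples.loc[ids].copy(),
                           list(self.design_formula), self.unannotated)


@dataclass
class ProbeMaskSet:
    """Probe exclusion lists; filtering removes the union of the four sets."""

    detection_fail: set = field(default_factory=set)
    sex_chrom: set = field(default_factory=set)
    cross_hybridizing: set = field(default_factory=set)
    snp_associated: set = field(default_factory=set)

    def union(self) -> set:
        return (set(self.detection_fail) | set(self.sex_chrom)
                | set(self.cross_hybridizing) | set(self.snp_associated))

    def categories(self) -> dict:
        return {
            "detection_fail": set(self.detection_fail),
            "sex_chrom": set(self.sex_chrom),
            "cross_hybridizing": set(self.cross_hybridizing),
            "snp_associated": set(self.snp_associated),
        }


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check and enrich a probe-annotation frame.

    Adds derived columns ``state_discordant`` (male and female chromatin-state
    labels differ) and ``regulatory_class`` (promoter / enhancer / other from
    the male-state label).  ``genes`` may be a ';'-joined string or a list.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns {missing}")
    ann = annotation.copy()
    if (ann["pos"] < 1).any():
        raise ValidationError("annotation positions must be >= 1 (1-based)")
    if ann["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe ids in annotation")
    if not ann["genes"].map(lambda g: isinstance(g, (list, tuple))).all():
        ann["genes"] = ann["genes"].fillna("").map(
            lambda g: [x for x in str(g).split(";") if x] if not isinstance(g, (list, tuple)) else list(g)
        )
    ann["state_discordant"] = ann["state_male"] != ann["state_female"]
    ann["regulatory_class"] = np.where(
        ann["state_male"].isin(PROMOTER_STATES), "promoter",
        np.where(ann["state_male"].isin(ENHANCER_STATES), "enhancer", "other"),
    )
    return ann


def read_annotation(path) -> pd.DataFrame:
    """Read a manifest-like TSV (probe_id, chrom, pos, genes, island_relation,
    state_male, state_female) into a validated annotation frame."""
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.loc[:, list(ANNOTATION_COLUMNS)].copy()
    out["genes"] = out["genes"].map(lambda g: ";".join(g) if isinstance(g, (list, tuple)) else g)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path, name_field: str = "name") -> pd.DataFrame:
    """Read a BED3+1 file (chrom, start, end, name); 0-based half-open."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chrom", "start", "end", name_field],
                      dtype={0: str})
    if (bed["end"] <= bed["start"]).any():
        raise ValidationError("BED intervals must satisfy start < end")
    return bed


# ---------------------------------------------------------------------------
# beta matrix I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(path, sample_sheet, name: str = "cohort",
                     design_formula=None, annotation: pd.DataFrame | None = None,
                     sep: str = "\t") -> CohortStudy:
    """Read a probes-x-samples beta TSV/CSV plus its sample sheet.

    First column of the matrix file must be ``probe_id``.  Values are
    validated to lie in [0, 1].  Probes absent from *annotation* are retained
    and recorded in ``study.unannotated``.
    """
    beta = pd.read_csv(path, sep=sep, index_col=0)
    beta.index = beta.index.astype(str)
    if isinstance(sample_sheet, pd.DataFrame):
        samples = sample_sheet.copy()
    else:
        samples = pd.read_csv(sample_sheet, sep=sep)
    study = CohortStudy(name, beta, samples,
                        list(design_formula) if design_formula else ["sex"])
    if annotation is not None:
        known = set(annotation["probe_id"])
        study.unannotated = frozenset(p for p in beta.index if p not in known)
        if study.unannotated:
            logger.info("%d probes absent from annotation in %s",
                        len(study.unannotated), name)
    return study


def write_beta_matrix(study: CohortStudy, matrix_path, sample_sheet_path=None,
                      sep: str = "\t") -> None:
    out = study.beta.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep=sep, float_format="%.10g")
    if sample_sheet_path is not None:
        study.samples.reset_index().to_csv(sample_sheet_path, sep=sep, index=False)


def load_cohort_config(path) -> dict:
    """Load a per-cohort YAML config: paths plus ordered formula terms."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "formula" in cfg and not isinstance(cfg["formula"], list):
        raise ValidationError("cohort config 'formula' must be a list of terms")
    return cfg


# ---------------------------------------------------------------------------
# probe filtering & intersection
# ---------------------------------------------------------------------------

def filter_probes(study: CohortStudy, masks: ProbeMaskSet) -> tuple[CohortStudy, dict]:
    """Drop the union of the mask sets from *study*.

    Mask ids not present in the study are ignored (count logged).  Returns the
    filtered study and the per-category removal counts.
    """
    present = set(study.beta.index)
    union = masks.union()
    unknown = union - present
    if unknown:
        logger.info("%d mask probes not present in %s", len(unknown), study.name)
    removed = {cat: len(ids & present) for cat, ids in masks.categories().items()}
    keep = study.beta.index[~study.beta.index.isin(union)]
    if len(keep) == 0:
        raise ValidationError("all probes filtered")
    removed["total"] = study.n_probes - len(keep)
    return study.subset_probes(keep), removed


def beta_to_m(beta, eps: float = EPS_BETA):
    """logit2 transform: m = log2(beta / (1 - beta)), beta clipped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit2: beta = 2**m / (1 + 2**m)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def intersect_probes(studies: list[CohortStudy], min_cohorts: int = 2
                     ) -> tuple[pd.Index, pd.DataFrame]:
    """Partition probes by cohort membership.

    Returns the probes present in at least *min_cohorts* cohorts (the meta
    set) and a boolean membership frame (probes x cohorts).
    """
    if min_cohorts < 2:
        raise ValidationError("min_cohorts must be >= 2")
    if min_cohorts > len(studies):
        raise ValidationError(
            f"min_cohorts={min_cohorts} exceeds number of studies ({len(studies)})")
    all_probes = pd.Index(sorted(set().union(*(s.beta.index for s in studies))))
    membership = pd.DataFrame(
        {s.name: all_probes.isin(s.beta.index) for s in studies}, index=all_probes)
    keep = membership.index[membership.sum(axis=1) >= min_cohorts]
    return keep, membership


# ---------------------------------------------------------------------------
# interval overlap (BED half-open vs 1-based CpG points)
# ---------------------------------------------------------------------------

def cpgs_in_intervals(annotation: pd.DataFrame, bed: pd.DataFrame) -> pd.Series:
    """Boolean Series (indexed by probe_id): CpG overlaps any BED interval.

    A CpG at 1-based position p overlaps [s, e) iff s <= p - 1 < e.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int)))
    hits = np.zeros(len(annotation), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(annotation["chrom"], annotation["pos"])):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            hits[i] = True
    return pd.Series(hits, index=annotation["probe_id"].to_numpy(), name="in_interval")
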