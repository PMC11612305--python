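"""Readers, writers and quality-control filters for methylation tables.

All tables are plain delimited text (tab by default, comma for ``.csv``)
with a header row. Beta and detection matrices are loci x samples with the
probe id in the first column; the phenotype table is indexed by sample id;
the probe annotation by probe id.

Every filter is a pure subset operation: surviving entries are bit-identical
to the input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "DetectionMatrix",
    "read_phenotype_table",
    "write_phenotype_table",
    "validate_phenotypes",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "filter_probes_by_detection",
    "filter_failed_samples",
    "mask_probes",
    "intersect_platforms",
]

PHENOTYPE_LABELS = frozenset({"aggressive", "non_aggressive"})
COHORTS = frozenset({"modeling", "training", "evaluation"})
_SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})
_ANNOTATION_COLUMNS = ("chromosome", "gene", "is_snp", "is_cpg", "enhancer", "tfbs")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


class _BoundedMatrix:
    """Loci x samples matrix of values in [0, 1]; NaN marks missing."""

    _kind = "value"

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        try:
            frame = frame.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric {self._kind} entry: {exc}") from exc
        values = frame.to_numpy()
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            r, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self._kind} {values[r, s]!r} outside [0, 1] at probe "
                f"{frame.index[r]!r}, sample {frame.columns[s]!r}")
        frame.index = frame.index.astype(str)
        frame.index.name = "probe_id"
        frame.columns = frame.columns.astype(str)
        self._frame = frame

    # -- accessors -----------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def probe_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def select_probes(self, probe_ids):
        return type(self)(self._frame.loc[list(probe_ids)])

    def select_samples(self, sample_ids):
        return type(self)(self._frame[list(sample_ids)])

    def equals(self, other) -> bool:
        return self._frame.equals(other._frame)

    # -- text round trip -----------------------------------------------------
    @classmethod
    def read(cls, path, orientation: str = "probes_by_samples", sep: str | None = None):
        """Read a delimited matrix; ``orientation='samples_by_probes'`` transposes."""
        if orientation not in ("probes_by_samples", "samples_by_probes"):
            raise ValidationError(f"unknown orientation {orientation!r}")
        try:
            frame = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if orientation == "samples_by_probes":
            frame = frame.T
        return cls(frame)

    def write(self, path, sep: str | None = None) -> None:
        self._frame.to_csv(path, sep=sep or _sep_for(path), float_format="%.10g")

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}({self.shape[0]} probes x {self.shape[1]} samples)"


class BetaMatrix(_BoundedMatrix):
    """Methylation beta values (methylation ratio per CpG locus) in [0, 1]."""

    _kind = "beta value"


class DetectionMatrix(_BoundedMatrix):
    """Per-entry detection p-values, same axes as the companion BetaMatrix."""

    _kind = "detection p-value"


def _check_axes(beta: BetaMatrix, det: DetectionMatrix) -> None:
    if beta.probe_ids != det.probe_ids or beta.sample_ids != det.sample_ids:
        raise ValidationError("beta and detection matrices have mismatched axes")


# ---------------------------------------------------------------------------
# phenotype / annotation tables
# ---------------------------------------------------------------------------

def validate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    if phenotypes.index.has_duplicates:
        dupes = phenotypes.index[phenotypes.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    if "label" not in phenotypes.columns:
        raise ValidationError("phenotype table requires a 'label' column")
    bad = set(phenotypes["label"]) - PHENOTYPE_LABELS
    if bad:
        raise ValidationError(f"unknown phenotype labels: {sorted(bad)}")
    if "cohort" in phenotypes.columns:
        bad = set(phenotypes["cohort"].dropna()) - COHORTS - {""}
        if bad:
            raise ValidationError(f"unknown cohort roles: {sorted(bad)}")
    return phenotypes


def read_phenotype_table(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return validate_phenotypes(df)


def write_phenotype_table(phenotypes: pd.DataFrame, path, sep: str | None = None) -> None:
    validate_phenotypes(phenotypes).to_csv(path, sep=sep or _sep_for(path))


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids in annotation: {dupes[:5]}")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    return annotation


def read_annotation(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0,
                     keep_default_na=False, dtype={"gene": str, "tfbs": str})
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    for col in ("is_snp", "is_cpg", "enhancer"):
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path, sep: str | None = None) -> None:
    out = validate_annotation(annotation).copy()
    for col in ("is_snp", "is_cpg", "enhancer"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep or _sep_for(path))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_probes_by_detection(beta: BetaMatrix, det: DetectionMatrix,
                               alpha: float = 0.05,
                               max_fail_fraction_per_probe: float = 0.0,
                               fail_if: str = "p_above") -> BetaMatrix:
    """Drop probes whose detection failure rate exceeds the tolerance.

    An observation *fails* detection when its p-value is >= ``alpha``
    (``fail_if='p_above'``, the conventional array reading); the opposite
    direction is available as ``fail_if='p_below'``. With the default
    tolerance of 0 a single failing observation removes the probe.
    """
    _check_axes(beta, det)
    if fail_if == "p_above":
        failed = det.values >= alpha
    elif fail_if == "p_below":
        failed = det.values < alpha
    else:
        raise ValidationError(f"fail_if must be 'p_above' or 'p_below', got {fail_if!r}")
    frac = failed.mean(axis=1)
    keep = frac <= max_fail_fraction_per_probe
    log.info("detection filter: %d of %d probes retained", int(keep.sum()), keep.size)
    return beta.select_probes(np.asarray(beta.probe_ids, dtype=object)[keep])


def filter_failed_samples(beta: BetaMatrix, det: DetectionMatrix | None,
                          alpha: float = 0.05,
                          max_failed_fraction: float = 0.10) -> BetaMatrix:
    """Drop samples with strictly more than ``max_failed_fraction`` failed probes."""
    if det is None:
        log.warning("no detection matrix supplied; sample filter is the identity")
        return beta
    _check_axes(beta, det)
    frac = (det.values >= alpha).mean(axis=0)
    keep = frac <= max_failed_fraction
    log.info("sample filter: %d of %d samples retained", int(keep.sum()), keep.size)
    return beta.select_samples(np.asarray(beta.sample_ids, dtype=object)[keep])


def mask_probes(beta: BetaMatrix, annotation: pd.DataFrame,
                masks=("snp", "non_cpg", "sex_chromosomes")) -> BetaMatrix:
    """Remove probes flagged by any enabled mask; input order is preserved."""
    validate_annotation(annotation)
    unknown = set(masks) - {"snp", "non_cpg", "sex_chromosomes"}
    if unknown:
        raise ValidationError(f"unknown masks: {sorted(unknown)}")
    missing = [p for p in beta.probe_ids if p not in annotation.index]
    if missing:
        raise ValidationError(f"probes missing from annotation: {missing[:10]}")
    ann = annotation.loc[beta.probe_ids]
    drop = np.zeros(len(ann), dtype=bool)
    if "snp" in masks:
        drop |= ann["is_snp"].to_numpy(dtype=bool)
    if "non_cpg" in masks:
        drop |= ~ann["is_cpg"].to_numpy(dtype=bool)
    if "sex_chromosomes" in masks:
        drop |= ann["chromosome"].isin(_SEX_CHROMOSOMES).to_numpy()
    keep_ids = [p for p, d in zip(beta.probe_ids, drop) if not d]
    return beta.select_probes(keep_ids)


def intersect_platforms(beta_a: BetaMatrix, beta_b: BetaMatrix):
    """Restrict both matrices to their shared probes, in ``beta_a``'s order."""
    shared = [p for p in beta_a.probe_ids if p in set(beta_b.probe_ids)]
    if not shared:
        raise ValidationError("no shared probes between the two matrices")
    return beta_a.select_probes(shared), beta_b.select_probes(shared)
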