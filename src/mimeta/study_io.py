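"""Readers and normalizers for multi-study case/control expression data.

All downstream statistics assume expression on the log2 scale, genes (not
probes) as row keys, and a two-level phenotype (``case`` / ``control``).
This module gets arbitrary tab-separated inputs into that shape:

* :func:`ensure_log2` detects raw-intensity matrices and log-transforms them;
* :func:`collapse_probes` summarizes many-to-one probe→gene maps by median;
* :func:`read_expression_study` joins a matrix with its phenotype table;
* :func:`filter_manifest` applies the four dataset-inclusion criteria used
  to assemble a case-vs-healthy microarray collection from a catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Matrices whose maximum exceeds this are assumed to be on a raw intensity
#: scale and are log2(x+1)-transformed.  Log2 microarray data rarely exceeds
#: ~20; raw intensities are in the hundreds to tens of thousands.
LOG_SCALE_MAX = 50.0

VALID_GROUPS = frozenset({"case", "control"})


class ValidationError(ValueError):
    """Input data violates a structural precondition."""


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus case/control assignment.

    Parameters
    ----------
    study_id:
        Identifier (e.g. a GEO accession) used to join against study
        metadata.
    values:
        genes × samples DataFrame of log2 expression.
    groups:
        Series mapping sample id → ``"case"`` or ``"control"``; every indexed
        sample must be a column of ``values``.
    """

    study_id: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = self.groups.index.difference(self.values.columns)
        if len(missing) > 0:
            raise ValidationError(
                f"{self.study_id}: samples in phenotype but not in matrix: "
                f"{list(missing)[:5]}"
            )
        bad = set(self.groups.unique()) - VALID_GROUPS
        if bad:
            raise ValidationError(f"{self.study_id}: unknown group labels {bad}")
        if not self.case_samples or not self.control_samples:
            raise ValidationError(
                f"{self.study_id}: need at least one case and one control sample"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise ValidationError(f"{self.study_id}: duplicate gene keys {list(dupes)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError(f"{self.study_id}: non-finite expression values")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class StudyMetadata:
    """Study-level covariates: arm sizes, country, years since the study."""

    study_id: str
    n_control: int
    n_case: int
    country: str
    study_age: float
    organism: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValidationError(f"{self.study_id}: both arms need >=1 sample")
        if self.study_age < 0:
            raise ValidationError(f"{self.study_id}: study_age must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass
class DatasetRecord:
    """One catalog entry tested against the inclusion criteria."""

    accession: str
    is_array: bool
    downloadable: bool
    organism: str
    design_case_vs_healthy: bool


@dataclass
class ProbeMap:
    """Many-to-one probe id → gene symbol mapping."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, g in self.entries.items() if not str(g).strip()]
        if empty:
            raise ValidationError(f"probes mapping to empty gene symbol: {empty[:5]}")


def ensure_log2(values: pd.DataFrame) -> pd.DataFrame:
    """Return ``values`` on the log2 scale.

    A matrix whose maximum exceeds :data:`LOG_SCALE_MAX` is treated as raw
    intensities and transformed element-wise to ``log2(x + 1)`` (the +1
    keeps zeros finite); anything else is assumed to be already
    log-transformed and is returned unchanged.
    """
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValidationError("expression matrix contains non-finite values")
    if arr.max() <= LOG_SCALE_MAX:
        return values
    if (arr < 0).any():
        raise ValidationError(
            "matrix looks untransformed (max > %.0f) but contains negative values"
            % LOG_SCALE_MAX
        )
    logger.info(
        "matrix max %.3g exceeds %.0f; applying log2(x+1)", arr.max(), LOG_SCALE_MAX
    )
    return pd.DataFrame(
        np.log2(arr + 1.0), index=values.index, columns=values.columns
    )


def collapse_probes(values: pd.DataFrame, probe_map: ProbeMap) -> pd.DataFrame:
    """Collapse a probe-keyed matrix to gene rows by element-wise median.

    Probes absent from the map are dropped (logged).  Median is robust to a
    single aberrant probe among several targeting the same gene.
    """
    mapping = pd.Series(dict(probe_map.entries))
    present = values.index.intersection(mapping.index)
    if len(present) == 0:
        raise ValidationError("no matrix probe is present in the probe map")
    dropped = values.index.difference(mapping.index)
    if len(dropped) > 0:
        logger.info("dropping %d unmapped probes", len(dropped))
    sub = values.loc[present]
    collapsed = sub.groupby(mapping.loc[present].to_numpy()).median()
    collapsed.index.name = values.index.name
    return collapsed


def read_expression_study(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    probe_map: ProbeMap | None = None,
    study_id: str | None = None,
) -> ExpressionStudy:
    """Load one study from a matrix TSV and a phenotype TSV.

    The matrix has row keys in the first column and sample ids in the first
    row; the phenotype table has columns ``sample_id`` and ``group``.
    Samples present in the matrix but unlabeled in the phenotype table are
    dropped with a warning.  The result is log2-scaled and, when a probe map
    is given, collapsed to gene rows.
    """
    matrix_path = Path(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(pheno.columns):
        raise ValidationError(
            f"{phenotype_path}: expected columns sample_id, group"
        )
    if pheno["sample_id"].duplicated().any():
        raise ValidationError(f"{phenotype_path}: duplicate sample ids")
    if values.columns.duplicated().any():
        raise ValidationError(f"{matrix_path}: duplicate sample ids")

    groups = pheno.set_index("sample_id")["group"]
    labeled = values.columns.intersection(groups.index)
    unlabeled = values.columns.difference(groups.index)
    if len(unlabeled) > 0:
        logger.warning(
            "%s: dropping %d samples without phenotype labels: %s",
            matrix_path.name,
            len(unlabeled),
            list(unlabeled)[:5],
        )
    values = values[labeled]
    groups = groups.loc[labeled]

    values = ensure_log2(values)
    if probe_map is not None:
        values = collapse_probes(values, probe_map)
    sid = study_id if study_id is not None else matrix_path.stem
    return ExpressionStudy(study_id=sid, values=values, groups=groups)


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read a GEO series-matrix style TSV, skipping ``!``-prefixed metadata."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="!")


def filter_manifest(records: Sequence[DatasetRecord]) -> list[DatasetRecord]:
    """Apply the four dataset-inclusion criteria, in order, with logging.

    Criteria: (1) array expression data; (2) original data downloadable;
    (3) human organism; (4) case-vs-healthy-control design.  Surviving
    counts are logged per stage so the selection funnel is inspectable.
    """
    stages = [
        ("array expression data", lambda r: r.is_array),
        ("data downloadable", lambda r: r.downloadable),
        (
            "human organism",
            lambda r: r.organism.strip().lower() in {"human", "homo sapiens"},
        ),
        ("case vs healthy control design", lambda r: r.design_case_vs_healthy),
    ]
    seen = set()
    for rec in records:
        if not rec.accession:
            raise ValidationError("manifest record with empty accession")
        if rec.accession in seen:
            raise ValidationError(f"duplicate accession {rec.accession}")
        seen.add(rec.accession)

    surviving = list(records)
    logger.info("manifest: %d records", len(surviving))
    for name, keep in stages:
        surviving = [r for r in surviving if keep(r)]
        logger.info("manifest after %r: %d records", name, len(surviving))
    return surviving


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a TSV with columns ``probe_id``, ``gene_symbol``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns probe_id, gene_symbol")
    return ProbeMap(entries=dict(zip(df["probe_id"], df["gene_symbol"])))


def read_manifest(path: str | Path) -> list[DatasetRecord]:
    """Read a dataset manifest CSV into :class:`DatasetRecord` rows."""
    df = pd.read_csv(path)
    required = {
        "accession",
        "is_array",
        "downloadable",
        "organism",
        "design_case_vs_healthy",
    }
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")

    def as_bool(x) -> bool:
        if isinstance(x, (bool, np.bool_)):
            return bool(x)
        return str(x).strip().lower() in {"true", "1", "yes"}

    return [
        DatasetRecord(
            accession=str(row.accession),
            is_array=as_bool(row.is_array),
            downloadable=as_bool(row.downloadable),
            organism=str(row.organism),
            design_case_vs_healthy=as_bool(row.design_case_vs_healthy),
        )
        for row in df.itertuples()
    ]


def read_metadata(path: str | Path) -> list[StudyMetadata]:
    """Read a study-metadata CSV (study_id, arm sizes, country, study_age)."""
    df = pd.read_csv(path)
    required = {"study_id", "n_control", "n_case", "country", "study_age"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    return [
        StudyMetadata(
            study_id=str(row.study_id),
            n_control=int(row.n_control),
            n_case=int(row.n_case),
            country=str(row.country),
            study_age=float(row.study_age),
            organism=str(getattr(row, "organism", "Homo sapiens")),
        )
        for row in df.itertuples()
    ]


def default_study_metadata() -> list[StudyMetadata]:
    """The packaged nine-study myocardial-infarction collection metadata."""
    from importlib.resources import files

    return read_metadata(files("mimeta.data").joinpath("study_metadata.csv"))
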