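"""Regulator-role classification and pipeline orchestration.

A regulator of myocardial infarction (MI) that is itself driven by
schizophrenia (SCZ) is classified from two attributes: its role toward MI
(promoter or inhibitor) and the direction in which SCZ drives it (activates
or deactivates).  Activating a promoter or deactivating an inhibitor pushes
the disease forward (harmful); the two complementary pairings oppose it
(protective).  Regulators live at several biological levels — genes, small
molecules, gene families, complexes — and are summarized per level.

:func:`run_pipeline` chains the stages end to end: load or simulate studies,
compute per-study effect sizes, pool per gene with heterogeneity-driven
model selection, regress effects on study moderators, classify the packaged
regulator roles, and write the merged per-gene report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import effects as effects_mod
from . import meta as meta_mod
from . import moderators as moderators_mod
from . import study_io
from .study_io import StudyMetadata, ValidationError

logger = logging.getLogger(__name__)

LEVELS = ("gene", "small_molecule", "gene_family", "complex")
#: Relationships below this reference count were filtered out upstream.
MIN_REFS = 3

Classification = Literal["harmful", "protective"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RegulatorRole:
    """One literature-derived MI regulator driven by SCZ."""

    name: str
    level: str
    mi_role: Literal["promoter", "inhibitor"]
    scz_effect: Literal["activates", "deactivates"]
    min_refs: int = MIN_REFS

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"{self.name}: unknown level {self.level!r}")
        if self.mi_role not in ("promoter", "inhibitor"):
            raise ValidationError(f"{self.name}: unknown mi_role {self.mi_role!r}")
        if self.scz_effect not in ("activates", "deactivates"):
            raise ValidationError(
                f"{self.name}: unknown scz_effect {self.scz_effect!r}"
            )
        if self.min_refs < MIN_REFS:
            raise ValidationError(
                f"{self.name}: min_refs {self.min_refs} below the confidence "
                f"filter of {MIN_REFS}"
            )


@dataclass
class ReportSummary:
    """Harmful/protective counts per biological level plus totals."""

    per_level: dict[str, dict[str, int]] = field(default_factory=dict)
    harmful: int = 0
    protective: int = 0

    @property
    def total(self) -> int:
        return self.harmful + self.protective

    def to_dict(self) -> dict:
        return {
            "per_level": self.per_level,
            "harmful": self.harmful,
            "protective": self.protective,
            "total": self.total,
        }


def classify_regulator(role: RegulatorRole) -> Classification:
    """Harmful iff SCZ activates an MI promoter or deactivates an MI inhibitor."""
    harmful = (role.mi_role == "promoter") == (role.scz_effect == "activates")
    return "harmful" if harmful else "protective"


def summarize_network(roles: Sequence[RegulatorRole]) -> ReportSummary:
    """Count harmful and protective regulators per biological level."""
    summary = ReportSummary(
        per_level={lvl: {"harmful": 0, "protective": 0} for lvl in LEVELS}
    )
    for role in roles:
        cls = classify_regulator(role)
        summary.per_level[role.level][cls] += 1
        if cls == "harmful":
            summary.harmful += 1
        else:
            summary.protective += 1
    return summary


def read_roles(path: str | Path) -> list[RegulatorRole]:
    """Read a roles TSV (columns name, level, mi_role, scz_effect, min_refs).

    Lines starting with ``#`` are comments.  The confidence filter
    (min_refs ≥ 3) and name uniqueness are enforced at load time.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "level", "mi_role", "scz_effect", "min_refs"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    if df["name"].duplicated().any():
        raise ValidationError(f"{path}: duplicate regulator names")
    return [
        RegulatorRole(
            name=str(r.name),
            level=str(r.level),
            mi_role=str(r.mi_role),
            scz_effect=str(r.scz_effect),
            min_refs=int(r.min_refs),
        )
        for r in df.itertuples(index=False)
    ]


def default_roles() -> list[RegulatorRole]:
    """The packaged 19-regulator roles table."""
    from importlib.resources import files

    return read_roles(files("mimeta.data").joinpath("regulator_roles.tsv"))


def merge_report(
    roles: Sequence[RegulatorRole],
    meta_df: pd.DataFrame,
    moderator_df: pd.DataFrame,
) -> pd.DataFrame:
    """Per-regulator report merging roles with meta and moderator results.

    Left-joined on the roles table, so non-gene regulators (small molecules,
    families, complexes) appear with empty statistical columns.  Columns
    mirror the per-gene results table: random-effects flag, contributing
    study count, pooled LFC and p, then one moderator p per factor.
    """
    rows = []
    meta_by_gene = meta_df.set_index("gene") if len(meta_df) else pd.DataFrame()
    mod_wide = (
        moderator_df.pivot(index="gene", columns="factor", values="p")
        if len(moderator_df)
        else pd.DataFrame()
    )
    for role in roles:
        row = {
            "name": role.name,
            "level": role.level,
            "mi_role": role.mi_role,
            "scz_effect": role.scz_effect,
            "classification": classify_regulator(role),
            "random_effects_model": np.nan,
            "n_study": np.nan,
            "effect_size_LFC": np.nan,
            "p_value": np.nan,
            "p_n_samples": np.nan,
            "p_country": np.nan,
            "p_study_age": np.nan,
        }
        if role.name in getattr(meta_by_gene, "index", []):
            m = meta_by_gene.loc[role.name]
            row.update(
                random_effects_model=int(m["model"] == "random"),
                n_study=int(m["k"]),
                effect_size_LFC=float(m["pooled_LFC"]),
                p_value=float(m["p"]),
            )
        if role.name in getattr(mod_wide, "index", []):
            p = mod_wide.loc[role.name]
            row.update(
                p_n_samples=float(p.get("n_samples", np.nan)),
                p_country=float(p.get("country", np.nan)),
                p_study_age=float(p.get("study_age", np.nan)),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config: dict | str | Path) -> tuple[ReportSummary, dict[str, Path]]:
    """Run every stage and write the outputs named in the run configuration.

    The configuration (mapping or YAML path) provides either ``studies_dir``
    (per-study expression/phenotype TSVs plus metadata.csv) or ``simulate``
    (a simulation specification), plus ``genes`` (list or file of symbols),
    optional ``roles`` and ``metadata`` paths (packaged defaults otherwise),
    ``out_dir``, ``seed``, and ``alpha``.

    Returns the role summary and a map of output names to written paths:
    effects.tsv, meta.tsv, moderators.tsv, report.tsv, summary.json.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: study acquisition ---------------------------------------
    try:
        if "simulate" in cfg:
            from . import synthetic

            sim_raw = dict(cfg["simulate"])
            sim_raw.setdefault("seed", cfg.get("seed", 0))
            sim_config = synthetic.config_from_dict(sim_raw)
            studies, truth = synthetic.simulate_collection(sim_config)
            metadata = list(sim_config.studies)
            truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        elif "studies_dir" in cfg:
            studies_dir = Path(cfg["studies_dir"])
            metadata = study_io.read_metadata(
                cfg.get("metadata", studies_dir / "metadata.csv")
            )
            studies = [
                study_io.read_expression_study(
                    studies_dir / f"{m.study_id}_expression.tsv",
                    studies_dir / f"{m.study_id}_phenotype.tsv",
                    study_id=m.study_id,
                )
                for m in metadata
            ]
        else:
            raise ValidationError("config needs either 'studies_dir' or 'simulate'")
    except (OSError, ValidationError) as exc:
        raise PipelineError(f"study acquisition: {exc}") from exc
    logger.info("stage study acquisition: %d studies", len(studies))

    # --- stage: gene list and roles --------------------------------------
    try:
        genes_cfg = cfg.get("genes")
        if genes_cfg is None:
            genes = sorted({g for s in studies for g in s.genes})
        elif isinstance(genes_cfg, (list, tuple)):
            genes = [str(g) for g in genes_cfg]
        else:
            genes = [
                line.strip()
                for line in Path(genes_cfg).read_text().splitlines()
                if line.strip()
            ]
        roles = (
            read_roles(cfg["roles"]) if "roles" in cfg else default_roles()
        )
    except (OSError, ValidationError) as exc:
        raise PipelineError(f"configuration: {exc}") from exc
    logger.info("stage configuration: %d genes, %d roles", len(genes), len(roles))

    # --- stage: effect sizes ---------------------------------------------
    try:
        effect_list = effects_mod.build_effect_table(studies, genes)
    except ValidationError as exc:
        raise PipelineError(f"effect sizes: {exc}") from exc
    effects_df = effects_mod.effects_to_frame(effect_list)
    logger.info("stage effect sizes: %d (gene, study) records", len(effects_df))

    # --- stage: meta-analysis ---------------------------------------------
    try:
        meta_df = meta_mod.meta_table(effect_list)
    except ValidationError as exc:
        raise PipelineError(f"meta-analysis: {exc}") from exc
    logger.info("stage meta-analysis: %d genes pooled", len(meta_df))

    # --- stage: moderator regression ---------------------------------------
    try:
        moderator_df = moderators_mod.moderator_table(
            effect_list, metadata, genes=list(meta_df["gene"])
        )
    except ValidationError as exc:
        raise PipelineError(f"moderator regression: {exc}") from exc
    logger.info(
        "stage moderator regression: %d genes", moderator_df["gene"].nunique()
    )

    # --- stage: report ------------------------------------------------------
    summary = summarize_network(roles)
    report_df = merge_report(roles, meta_df, moderator_df)
    paths = {
        "effects.tsv": out_dir / "effects.tsv",
        "meta.tsv": out_dir / "meta.tsv",
        "moderators.tsv": out_dir / "moderators.tsv",
        "report.tsv": out_dir / "report.tsv",
        "summary.json": out_dir / "summary.json",
    }
    effects_df.to_csv(paths["effects.tsv"], sep="\t", index=False)
    meta_df.to_csv(paths["meta.tsv"], sep="\t", index=False)
    moderator_df.to_csv(paths["moderators.tsv"], sep="\t", index=False)
    report_df.to_csv(paths["report.tsv"], sep="\t", index=False)
    with open(paths["summary.json"], "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
    logger.info(
        "stage report: %d regulators (%d harmful, %d protective)",
        summary.total,
        summary.harmful,
        summary.protective,
    )
    return summary, paths
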