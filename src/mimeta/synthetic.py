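"""Synthetic multi-study case/control expression collections with known truth.

The generator emulates a small collection of independent case/control
expression studies of the kind pooled in a myocardial-infarction
meta-analysis: unequal arm sizes per study, a per-gene true pooled effect
``mu`` on the log2 scale, between-study heterogeneity variance ``tau2``,
optional study-level moderator effects, and Gaussian per-sample noise.

For gene *g* in study *i* the realized study effect is

    theta_gi ~ Normal(mu_g + X_i . beta_g, tau2_g)

with X_i = (total sample size, country code, study age).  Control samples
are Normal(baseline, sd^2) and case samples Normal(baseline + theta_gi,
sd^2).  Every theta_gi is recorded in a truth table so downstream estimators
can be checked against the values they should recover.

Randomness is keyed by one integer seed; each (gene, study) pair gets an
independent, deterministically derived substream, so regeneration with the
same seed is bit-identical and adding a gene does not perturb the draws of
another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .study_io import ExpressionStudy, StudyMetadata, ValidationError
from .moderators import encode_covariates

logger = logging.getLogger(__name__)

#: Typical bulk microarray log2 intensity around which samples are centered.
DEFAULT_BASELINE = 8.0
#: Per-sample log2 noise standard deviation typical of bulk array data.
DEFAULT_SAMPLE_SD = 1.0


@dataclass
class GeneSpec:
    """True parameters for one simulated gene.

    ``beta`` gives the moderator coefficients, in log2 units per covariate
    unit, for (total sample size, country code, study age).
    """

    gene: str
    mu: float
    tau2: float = 0.0
    beta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValidationError(f"{self.gene}: tau2 must be >= 0")
        if len(self.beta) != 3:
            raise ValidationError(f"{self.gene}: beta must have 3 entries")


@dataclass
class SimulationConfig:
    """Full specification of one simulated study collection."""

    studies: Sequence[StudyMetadata]
    genes: Sequence[GeneSpec]
    baseline_mean: float = DEFAULT_BASELINE
    sample_sd: float = DEFAULT_SAMPLE_SD
    seed: int = 0
    #: study_id -> gene symbols absent from that study's platform,
    #: emulating genes measured by fewer than all studies.
    dropout: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_sd <= 0:
            raise ValidationError("sample_sd must be > 0")
        if not self.studies:
            raise ValidationError("at least one study required")
        if not self.genes:
            raise ValidationError("at least one gene required")
        for s in self.studies:
            if s.n_case < 2 or s.n_control < 2:
                raise ValidationError(
                    f"{s.study_id}: simulation needs >=2 samples per arm"
                )
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study_id in simulation config")
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene in simulation config")
        unknown = set(self.dropout) - set(ids)
        if unknown:
            raise ValidationError(f"dropout refers to unknown studies {unknown}")


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Generate expression studies and the truth table of realized effects.

    Returns
    -------
    studies:
        One :class:`ExpressionStudy` per configured study, genes × samples.
    truth:
        DataFrame with one row per (gene, study) pair actually simulated:
        columns ``gene, study_id, theta, mu, tau2, beta_n, beta_country,
        beta_age``.
    """
    design = encode_covariates(list(config.studies))
    # Moderator columns in GeneSpec.beta order (no intercept).
    X = design[["n_samples", "country", "study_age"]].to_numpy(dtype=float)

    studies: list[ExpressionStudy] = []
    truth_rows: list[dict] = []
    for i, meta in enumerate(config.studies):
        absent = set(config.dropout.get(meta.study_id, ()))
        sample_ids = [f"{meta.study_id}_ctl{j}" for j in range(meta.n_control)] + [
            f"{meta.study_id}_case{j}" for j in range(meta.n_case)
        ]
        groups = pd.Series(
            ["control"] * meta.n_control + ["case"] * meta.n_case, index=sample_ids
        )
        rows = {}
        for g, spec in enumerate(config.genes):
            if spec.gene in absent:
                continue
            # Independent substream per (gene, study): regeneration is
            # bit-identical and insensitive to which other pairs are drawn.
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(config.seed, g, i))
            )
            mean_effect = spec.mu + float(X[i] @ np.asarray(spec.beta))
            theta = mean_effect + np.sqrt(spec.tau2) * rng.standard_normal()
            control = config.baseline_mean + config.sample_sd * rng.standard_normal(
                meta.n_control
            )
            case = (
                config.baseline_mean
                + theta
                + config.sample_sd * rng.standard_normal(meta.n_case)
            )
            rows[spec.gene] = np.concatenate([control, case])
            truth_rows.append(
                {
                    "gene": spec.gene,
                    "study_id": meta.study_id,
                    "theta": theta,
                    "mu": spec.mu,
                    "tau2": spec.tau2,
                    "beta_n": spec.beta[0],
                    "beta_country": spec.beta[1],
                    "beta_age": spec.beta[2],
                }
            )
        if not rows:
            raise ValidationError(f"{meta.study_id}: every gene dropped out")
        values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
        values.index.name = "gene"
        studies.append(
            ExpressionStudy(study_id=meta.study_id, values=values, groups=groups)
        )
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "simulated %d studies x %d genes (seed=%d)",
        len(studies),
        len(config.genes),
        config.seed,
    )
    return studies, truth


def write_collection(
    out_dir: str | Path,
    studies: Sequence[ExpressionStudy],
    truth: pd.DataFrame,
    metadata: Sequence[StudyMetadata],
) -> None:
    """Write a simulated collection as per-study TSVs plus metadata and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study in studies:
        study.values.rename_axis("id").to_csv(
            out / f"{study.study_id}_expression.tsv", sep="\t"
        )
        pheno = pd.DataFrame(
            {"sample_id": study.groups.index, "group": study.groups.to_numpy()}
        )
        pheno.to_csv(out / f"{study.study_id}_phenotype.tsv", sep="\t", index=False)
    meta_df = pd.DataFrame(
        {
            "study_id": [m.study_id for m in metadata],
            "n_control": [m.n_control for m in metadata],
            "n_case": [m.n_case for m in metadata],
            "country": [m.country for m in metadata],
            "study_age": [m.study_age for m in metadata],
            "organism": [m.organism for m in metadata],
        }
    )
    meta_df.to_csv(out / "metadata.csv", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    logger.info("wrote %d studies to %s", len(studies), out)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON mapping.

    ``studies: default`` selects the packaged nine-study metadata.
    """
    from .study_io import default_study_metadata

    studies_raw = raw.get("studies", "default")
    if studies_raw == "default":
        studies = default_study_metadata()
    else:
        studies = [
            StudyMetadata(
                study_id=str(s["study_id"]),
                n_control=int(s["n_control"]),
                n_case=int(s["n_case"]),
                country=str(s.get("country", "NA")),
                study_age=float(s.get("study_age", 0.0)),
                organism=str(s.get("organism", "Homo sapiens")),
            )
            for s in studies_raw
        ]
    genes = [
        GeneSpec(
            gene=str(g["gene"]),
            mu=float(g.get("mu", 0.0)),
            tau2=float(g.get("tau2", 0.0)),
            beta=tuple(float(b) for b in g.get("beta", (0.0, 0.0, 0.0))),
        )
        for g in raw["genes"]
    ]
    return SimulationConfig(
        studies=studies,
        genes=genes,
        baseline_mean=float(raw.get("baseline_mean", DEFAULT_BASELINE)),
        sample_sd=float(raw.get("sample_sd", DEFAULT_SAMPLE_SD)),
        seed=int(raw.get("seed", 0)),
        dropout={k: list(v) for k, v in raw.get("dropout", {}).items()},
    )
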