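"""Per-study, per-gene effect sizes from case/control log2 expression.

The effect size is the log2 fold-change (LFC): the difference in mean log2
expression, case minus control.  Its variance uses the Welch (unpooled)
form, s_case^2/n_case + s_control^2/n_control, which stays valid under
unequal group variances; the inverse variance is the study's meta-analysis
weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .study_io import ExpressionStudy, ValidationError

logger = logging.getLogger(__name__)

#: Floor for the variance of an effect.  Constant probes would otherwise
#: yield v = 0 and an infinite weight; flooring keeps the gene in the
#: analysis with a finite (capped) weight.
VARIANCE_FLOOR = 1e-8


class GeneAbsentError(KeyError):
    """The requested gene is not measured in this study."""


@dataclass
class GeneEffect:
    """One study's effect size for one gene.

    ``T`` is the log2 fold-change (case mean − control mean), ``v`` its
    variance, and ``W = 1/v`` the inverse-variance weight.
    """

    gene: str
    study_id: str
    T: float
    v: float
    W: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValidationError(f"{self.gene}/{self.study_id}: v must be > 0")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError(
                f"{self.gene}/{self.study_id}: need >=2 samples per arm"
            )


def effect(gene: str, study_id: str, T: float, v: float,
           n_case: int = 2, n_control: int = 2) -> GeneEffect:
    """Construct a :class:`GeneEffect` with the weight derived from ``v``."""
    return GeneEffect(gene=gene, study_id=study_id, T=float(T), v=float(v),
                      W=1.0 / float(v), n_case=n_case, n_control=n_control)


def compute_study_effect(study: ExpressionStudy, gene: str) -> GeneEffect:
    """Compute one gene's LFC effect size and variance in one study.

    Raises
    ------
    GeneAbsentError
        If the gene is not a row of the study's matrix; callers skip the
        study, shrinking the gene's contributing-study count.
    ValidationError
        If either arm has fewer than two samples.
    """
    if gene not in study.values.index:
        raise GeneAbsentError(gene)
    case = study.values.loc[gene, study.case_samples].to_numpy(dtype=float)
    control = study.values.loc[gene, study.control_samples].to_numpy(dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValidationError(
            f"{study.study_id}: effect-size variance needs >=2 samples per arm"
        )
    T = case.mean() - control.mean()
    v = case.var(ddof=1) / len(case) + control.var(ddof=1) / len(control)
    if v < VARIANCE_FLOOR:
        logger.warning(
            "%s/%s: variance %.3g floored at %.0e (near-constant values)",
            gene,
            study.study_id,
            v,
            VARIANCE_FLOOR,
        )
        v = VARIANCE_FLOOR
    return GeneEffect(
        gene=gene,
        study_id=study.study_id,
        T=float(T),
        v=float(v),
        W=1.0 / float(v),
        n_case=len(case),
        n_control=len(control),
    )


def build_effect_table(
    studies: Sequence[ExpressionStudy], genes: Sequence[str]
) -> list[GeneEffect]:
    """Compute effects for every (gene, study) pair where the gene is present.

    A gene missing from a study's platform simply contributes no record for
    that study, so per-gene study counts can differ across genes.
    """
    if not studies:
        raise ValidationError("at least one study required")
    out: list[GeneEffect] = []
    for gene in genes:
        k = 0
        for study in studies:
            try:
                out.append(compute_study_effect(study, gene))
                k += 1
            except GeneAbsentError:
                continue
        if k == 0:
            logger.info("%s: absent from every study", gene)
        else:
            logger.debug("%s: %d contributing studies", gene, k)
    return out


def effects_to_frame(effects: Sequence[GeneEffect]) -> pd.DataFrame:
    """Tabulate effects with columns gene, study_id, T, v, W, n_case, n_control."""
    return pd.DataFrame(
        {
            "gene": [e.gene for e in effects],
            "study_id": [e.study_id for e in effects],
            "T": [e.T for e in effects],
            "v": [e.v for e in effects],
            "W": [e.W for e in effects],
            "n_case": [e.n_case for e in effects],
            "n_control": [e.n_control for e in effects],
        }
    )


def effects_from_frame(df: pd.DataFrame) -> list[GeneEffect]:
    """Inverse of :func:`effects_to_frame` (reads an effects TSV)."""
    return [
        GeneEffect(
            gene=str(r.gene),
            study_id=str(r.study_id),
            T=float(r.T),
            v=float(r.v),
            W=1.0 / float(r.v),
            n_case=int(r.n_case),
            n_control=int(r.n_control),
        )
        for r in df.itertuples()
    ]
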