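"""Meta-regression of per-study effect sizes on study-level moderators.

Per gene, the study effect sizes T_i are regressed by ordinary least
squares on three study-level covariates — total sample size, country
(encoded as a single integer label), and study age in years — and a
two-sided t-test p-value is reported per covariate.

Country is a single encoded column rather than one-hot dummies: with
collections of fewer than ten studies spanning several countries, dummy
coding exhausts the residual degrees of freedom, and the report format
carries exactly one p-value per factor.  The label order is alphabetical
and arbitrary, a documented limitation of this encoding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effects import GeneEffect
from .study_io import StudyMetadata, ValidationError

logger = logging.getLogger(__name__)

FACTORS = ("n_samples", "country", "study_age")

#: Minimum studies for a full fit: intercept + 3 covariates + 1 residual df.
MIN_STUDIES = 5

#: Residual mean square below which the fit is treated as exact
#: (perfect-fit limit: p reported as 0 with a warning).
PERFECT_FIT_MSE = 1e-20


@dataclass
class FactorStats:
    """One covariate's OLS estimate; fields are NaN when unavailable."""

    coef: float = math.nan
    se: float = math.nan
    t: float = math.nan
    p: float = math.nan


@dataclass
class ModeratorResult:
    """Per-gene meta-regression outcome, one :class:`FactorStats` per factor."""

    gene: str
    factors: dict[str, FactorStats] = field(default_factory=dict)
    k_used: int = 0
    insufficient_data: bool = False


def encode_covariates(metadata: Sequence[StudyMetadata]) -> pd.DataFrame:
    """Design matrix: intercept, total sample size, country label, study age.

    Countries are mapped to integer labels in alphabetical order of the
    distinct names, starting at 0.  Row order matches the input; the index
    is the study id.
    """
    if not metadata:
        raise ValidationError("no study metadata supplied")
    countries = sorted({m.country for m in metadata})
    code = {c: i for i, c in enumerate(countries)}
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "n_samples": [float(m.n_total) for m in metadata],
            "country": [float(code[m.country]) for m in metadata],
            "study_age": [float(m.study_age) for m in metadata],
        },
        index=pd.Index([m.study_id for m in metadata], name="study_id"),
    )


def fit_moderators(
    gene: str,
    effects: Sequence[GeneEffect],
    metadata: Sequence[StudyMetadata],
) -> ModeratorResult:
    """OLS of one gene's study effects on the moderator design matrix.

    Effects and metadata are joined on study id.  Constant (zero-variance)
    covariates are dropped and reported with NaN statistics.  Fewer than
    :data:`MIN_STUDIES` joined studies yields an insufficient-data result
    with all statistics NaN rather than an error, so thinly measured genes
    still appear in reports.
    """
    gene_effects = [e for e in effects if e.gene == gene]
    design = encode_covariates(list(metadata))
    available = [e for e in gene_effects if e.study_id in design.index]
    dropped = len(gene_effects) - len(available)
    if dropped:
        logger.warning("%s: %d effects lack metadata and were dropped", gene, dropped)

    result = ModeratorResult(
        gene=gene, factors={f: FactorStats() for f in FACTORS}, k_used=len(available)
    )
    if len(available) < MIN_STUDIES:
        logger.info(
            "%s: %d studies < %d required for a full moderator fit",
            gene,
            len(available),
            MIN_STUDIES,
        )
        result.insufficient_data = True
        return result

    y = np.array([e.T for e in available])
    X = design.loc[[e.study_id for e in available]]

    constant = [f for f in FACTORS if X[f].nunique() <= 1]
    if constant:
        logger.warning("%s: constant covariates dropped: %s", gene, constant)
    kept = [f for f in FACTORS if f not in constant]
    fit = sm.OLS(y, X[["intercept", *kept]]).fit()

    perfect = fit.mse_resid < PERFECT_FIT_MSE or not np.isfinite(fit.mse_resid)
    if perfect:
        logger.warning("%s: perfect fit (zero residuals); p-values are limiting", gene)
    for f in kept:
        coef = float(fit.params[f])
        if perfect:
            # Zero residual variance: the t statistic diverges for any
            # nonzero coefficient; report the limiting p-value.
            nonzero = abs(coef) > 1e-10
            result.factors[f] = FactorStats(
                coef=coef,
                se=0.0,
                t=math.copysign(math.inf, coef) if nonzero else 0.0,
                p=0.0 if nonzero else 1.0,
            )
        else:
            result.factors[f] = FactorStats(
                coef=coef,
                se=float(fit.bse[f]),
                t=float(fit.tvalues[f]),
                p=float(fit.pvalues[f]),
            )
    return result


def moderator_table(
    effects: Sequence[GeneEffect],
    metadata: Sequence[StudyMetadata],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format moderator report: one row per (gene, factor).

    Columns: gene, factor, coef, se, t, p, k_used.
    """
    if genes is None:
        seen = []
        for e in effects:
            if e.gene not in seen:
                seen.append(e.gene)
        genes = seen
    rows = []
    for gene in genes:
        res = fit_moderators(gene, effects, metadata)
        for f in FACTORS:
            fs = res.factors[f]
            rows.append(
                {
                    "gene": gene,
                    "factor": f,
                    "coef": fs.coef,
                    "se": fs.se,
                    "t": fs.t,
                    "p": fs.p,
                    "k_used": res.k_used,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "factor", "coef", "se", "t", "p", "k_used"]
    )
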