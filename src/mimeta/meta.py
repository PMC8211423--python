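"""Inverse-variance meta-analysis with heterogeneity-driven model selection.

For one gene with effects T_i and weights W_i = 1/v_i across k studies:

    Q   = sum(W_i T_i^2) - (sum(W_i T_i))^2 / sum(W_i)      (Cochran's Q)
    df  = k - 1
    I^2 = (Q - df)/Q if Q > df else 0

When Q <= df the observed dispersion is no larger than expected under
homogeneity, I^2 is set to zero, and the fixed-effect model is selected;
otherwise the random-effects model is used with the DerSimonian-Laird
moment estimator

    tau^2 = max(0, (Q - df) / C),   C = sum(W_i) - sum(W_i^2)/sum(W_i)

and re-weighting W*_i = 1/(v_i + tau^2).  The pooled estimate is the
weighted mean, its standard error (sum of weights)^(-1/2), and significance
is a two-sided z-test on pooled/se.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import GeneEffect
from .study_io import ValidationError

logger = logging.getLogger(__name__)

Model = Literal["fixed", "random"]


@dataclass
class MetaResult:
    """Pooled per-gene meta-analysis outcome."""

    gene: str
    k: int
    Q: float
    df: int
    ISq: float
    tau2: float
    model: Model
    pooled: float
    se: float
    z: float
    p: float


def _arrays(effects: Sequence[GeneEffect]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValidationError("no effects supplied")
    genes = {e.gene for e in effects}
    if len(genes) > 1:
        raise ValidationError(f"effects span multiple genes: {sorted(genes)}")
    T = np.array([e.T for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return T, v


def cochran_q(effects: Sequence[GeneEffect]) -> float:
    """Cochran's Q: inverse-variance weighted dispersion of study effects."""
    T, v = _arrays(effects)
    W = 1.0 / v
    q = float(np.sum(W * T**2) - np.sum(W * T) ** 2 / np.sum(W))
    # Guard against tiny negative values from floating-point cancellation.
    return max(q, 0.0)


def isq(Q: float, k: int) -> tuple[int, float]:
    """Degrees of freedom and I² heterogeneity fraction.

    I² = (Q − df)/Q measures the share of total variation attributable to
    between-study heterogeneity; it is clamped to 0 when Q ≤ df (no more
    dispersion than chance under homogeneity).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if Q < 0:
        raise ValidationError("Q must be >= 0")
    df = k - 1
    if Q > df:
        return df, (Q - df) / Q
    return df, 0.0


def select_model(Q: float, df: int) -> Model:
    """Fixed-effect iff Q ≤ df (boundary inclusive), else random-effects."""
    if df < 0:
        raise ValidationError("df must be >= 0")
    return "fixed" if Q <= df else "random"


def pool(effects: Sequence[GeneEffect], model: Model) -> MetaResult:
    """Inverse-variance pool under the given model.

    Fixed: weights 1/v_i, tau² = 0.  Random: DerSimonian–Laird tau² and
    weights 1/(v_i + tau²).  Requires ≥2 effects for random, ≥1 for fixed.
    """
    T, v = _arrays(effects)
    k = len(T)
    if model == "random" and k < 2:
        raise ValidationError("random-effects pooling needs >=2 studies")
    Q = cochran_q(effects)
    df, ISq = isq(Q, k)

    if model == "fixed":
        tau2 = 0.0
    else:
        W = 1.0 / v
        C = float(np.sum(W) - np.sum(W**2) / np.sum(W))
        tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    Wstar = 1.0 / (v + tau2)
    pooled = float(np.sum(Wstar * T) / np.sum(Wstar))
    se = float(np.sum(Wstar) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene=effects[0].gene,
        k=k,
        Q=Q,
        df=df,
        ISq=ISq,
        tau2=tau2,
        model=model,
        pooled=pooled,
        se=se,
        z=float(z),
        p=p,
    )


def meta_analyze_gene(effects: Sequence[GeneEffect]) -> MetaResult:
    """Full per-gene analysis: Q, df, I², model selection, pooling."""
    if len(effects) < 2:
        raise ValidationError("meta-analysis needs >=2 studies")
    Q = cochran_q(effects)
    df, _ = isq(Q, len(effects))
    model = select_model(Q, df)
    return pool(effects, model)


def meta_table(effects: Sequence[GeneEffect], min_k: int = 2) -> pd.DataFrame:
    """Run the per-gene meta-analysis over a mixed-gene effect list.

    Genes with fewer than ``min_k`` contributing studies are skipped with a
    log message.  Output columns mirror the per-gene meta-analysis report:
    gene, k, Q, df, ISq, tau2, model, pooled_LFC, se, z, p.
    """
    by_gene: dict[str, list[GeneEffect]] = {}
    for e in effects:
        by_gene.setdefault(e.gene, []).append(e)
    rows = []
    for gene, effs in by_gene.items():
        if len(effs) < min_k:
            logger.info("%s: only %d studies, skipping meta-analysis", gene, len(effs))
            continue
        r = meta_analyze_gene(effs)
        rows.append(
            {
                "gene": r.gene,
                "k": r.k,
                "Q": r.Q,
                "df": r.df,
                "ISq": r.ISq,
                "tau2": r.tau2,
                "model": r.model,
                "pooled_LFC": r.pooled,
                "se": r.se,
                "z": r.z,
                "p": r.p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "k",
            "Q",
            "df",
            "ISq",
            "tau2",
            "model",
            "pooled_LFC",
            "se",
            "z",
            "p",
        ],
    )
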