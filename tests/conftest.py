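import numpy as np
import pandas as pd
import pytest

from mimeta import ExpressionStudy, GeneSpec, SimulationConfig, default_study_metadata
from mimeta.effects import GeneEffect


@pytest.fixture(scope="session")
def nine_study_metadata():
    """The packaged nine-study collection metadata (unequal arm sizes)."""
    return default_study_metadata()


@pytest.fixture
def tiny_study():
    """2 genes x 4 samples, 2 cases and 2 controls, already on log2 scale."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0],
            "s2": [3.0, 7.0],
            "s3": [2.0, 6.0],
            "s4": [4.0, 8.0],
        },
        index=["G1", "G2"],
    )
    groups = pd.Series(
        {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    )
    return ExpressionStudy(study_id="tiny", values=values, groups=groups)


def make_effects(pairs, gene="g"):
    """GeneEffects from (T, v) pairs, one synthetic study id per entry."""
    return [
        GeneEffect(
            gene=gene,
            study_id=f"s{i}",
            T=float(t),
            v=float(v),
            W=1.0 / float(v),
            n_case=2,
            n_control=2,
        )
        for i, (t, v) in enumerate(pairs)
    ]


def write_study_tsvs(tmp_path, values, groups, stem="study"):
    """Write a matrix + phenotype TSV pair and return the two paths."""
    matrix_path = tmp_path / f"{stem}_expression.tsv"
    pheno_path = tmp_path / f"{stem}_phenotype.tsv"
    values.rename_axis("id").to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}).to_csv(
        pheno_path, sep="\t", index=False
    )
    return matrix_path, pheno_path


def brute_force_meta(T, v):
    """Plain-Python reference for Q, df, I2, DL tau2, pooled, se.

    Written with explicit loops so it shares no code path with the package.
    """
    k = len(T)
    W = [1.0 / vi for vi in v]
    sw = sum(W)
    swt = sum(wi * ti for wi, ti in zip(W, T))
    swt2 = sum(wi * ti * ti for wi, ti in zip(W, T))
    Q = swt2 - swt * swt / sw
    if Q < 0:
        Q = 0.0
    df = k - 1
    i2 = (Q - df) / Q if Q > df else 0.0
    if Q <= df:
        model = "fixed"
        tau2 = 0.0
    else:
        model = "random"
        C = sw - sum(wi * wi for wi in W) / sw
        tau2 = (Q - df) / C
        if tau2 < 0:
            tau2 = 0.0
    Ws = [1.0 / (vi + tau2) for vi in v]
    sws = sum(Ws)
    pooled = sum(wi * ti for wi, ti in zip(Ws, T)) / sws
    se = sws ** -0.5
    return {
        "Q": Q,
        "df": df,
        "ISq": i2,
        "tau2": tau2,
        "model": model,
        "pooled": pooled,
        "se": se,
    }


@pytest.fixture
def one_gene_config(nine_study_metadata):
    """Factory for single-gene simulation configs over the nine studies."""

    def _make(mu=0.7, tau2=0.0, sample_sd=1.0, seed=0, beta=(0.0, 0.0, 0.0)):
        return SimulationConfig(
            studies=nine_study_metadata,
            genes=[GeneSpec("G1", mu=mu, tau2=tau2, beta=beta)],
            sample_sd=sample_sd,
            seed=seed,
        )

    return _make
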