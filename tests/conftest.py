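import numpy as np
import pandas as pd
import pytest

from grafttx.expression import ExpressionMatrix, SampleDesign, aggregate_replicates
from grafttx.simulate import SimConfig, generate_expression


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        pd.DataFrame(
            [[0.0, 1.5], [10.0, 2.0], [3.25, 0.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def tiny_design():
    rows = [
        ("s1", "P_hybrida", "intact", 0, 1),
        ("s2", "P_hybrida", "interfamily", 3, 1),
    ]
    return SampleDesign(
        pd.DataFrame(
            rows, columns=["sample_id", "species", "treatment", "time_dag", "replicate"]
        ).set_index("sample_id")
    )


def condition_matrix(series: dict[str, dict[tuple[str, int], float] | tuple[float, float, float]]):
    """Build a one-species ConditionMatrix from per-gene trajectories.

    Values may be a full condition dict or an (x0, x3, x7) interfamily
    triple (other treatments flat at x0).
    """
    rows = {}
    for gene, spec in series.items():
        if isinstance(spec, tuple):
            x0, x3, x7 = spec
            spec = {("intact", 0): x0, ("interfamily", 3): x3, ("interfamily", 7): x7,
                    ("self", 3): x0, ("self", 7): x0, ("wound", 3): x0, ("wound", 7): x0}
        rows[gene] = {("P_hybrida",) + k: v for k, v in spec.items()}
    df = pd.DataFrame(rows).T
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=("species", "treatment", "time_dag"))
    from grafttx.expression import ConditionMatrix

    return ConditionMatrix(df)


@pytest.fixture
def make_condition_matrix():
    return condition_matrix


@pytest.fixture(scope="session")
def noiseless_bundle():
    cfg = SimConfig(n_genes=300, noise_sd=0.0, replicates=2, homolog_coverage=1.0,
                    n_decoys=1, seed=5)
    bundles, truth = generate_expression(cfg)
    conds = {sp: aggregate_replicates(m, d) for sp, (m, d) in bundles.items()}
    return cfg, bundles, conds, truth
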