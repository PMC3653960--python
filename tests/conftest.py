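import numpy as np
import pandas as pd
import pytest

from zcombine import ExpressionExperiment, SimulationConfig, simulate_experiment


@pytest.fixture
def tiny_experiment():
    """1 gene, control {0,1,2} vs one compound {1,2,3} (hand-checkable t)."""
    expr = pd.DataFrame(
        [[0.0, 1.0, 2.0, 1.0, 2.0, 3.0]],
        index=pd.Index(["g0001"], name="gene_id"),
        columns=["c1", "c2", "c3", "a1", "a2", "a3"],
    )
    arms = pd.Series(
        ["control"] * 3 + ["compound_1"] * 3,
        index=expr.columns, name="arm",
    )
    return ExpressionExperiment(expr=expr, arm_of_sample=arms)


@pytest.fixture
def null_experiment_k20():
    """All-null shared-control design: 4,000 genes, 3 compounds, 20 reps."""
    cfg = SimulationConfig(
        n_genes=4000, n_degs=0, n_compounds=3, replicates_per_arm=20, seed=42
    )
    experiment, _ = simulate_experiment(cfg)
    return experiment


@pytest.fixture
def small_threearm_experiment():
    """2 compounds + control, 2 replicates each: exhaustively permutable."""
    rng = np.random.default_rng(11)
    expr = pd.DataFrame(
        rng.normal(size=(3, 6)),
        index=pd.Index(["g0001", "g0002", "g0003"], name="gene_id"),
        columns=["c1", "c2", "a1", "a2", "b1", "b2"],
    )
    arms = pd.Series(
        ["control", "control", "compound_1", "compound_1",
         "compound_2", "compound_2"],
        index=expr.columns, name="arm",
    )
    return ExpressionExperiment(expr=expr, arm_of_sample=arms)
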