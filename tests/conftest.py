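import numpy as np
import pandas as pd
import pytest

from mirherit.containers import ExpressionMatrix, TargetSet, TargetSetCollection
from mirherit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structurally complete study conditions for fast tests."""
    return SimulationConfig(
        n_genes=600,
        n_mirnas=24,
        n_mirtrons=6,
        mean_targets_per_mirna=40,
        n_trios=30,
        n_unrelated=60,
        n_snps=120,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture
def five_gene_expr():
    """Hand-rankable single-sample expression column."""
    return pd.Series({"g1": 10.0, "g2": 20.0, "g3": 30.0, "g4": 40.0, "g5": 50.0})


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples ExpressionMatrix with metadata."""
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [3.0, 2.0, 1.0]},
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {"population": ["P1", "P1"], "role": ["unrelated", "unrelated"]},
        index=["s1", "s2"],
    )
    return ExpressionMatrix(values, meta)


def make_targets(*sets, classes=None):
    classes = classes or {}
    return TargetSetCollection(
        TargetSet(name, frozenset(genes), classes.get(name, "conventional"))
        for name, genes in sets
    )
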