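import numpy as np
import pandas as pd
import pytest

import txrescue as tx


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated four-group cohort shared across read-only tests."""
    cfg = tx.SimConfig(n_genes=300, n_hard_targets=20, seed=42)
    matrix, truth = tx.generate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    """A tiny handmade two-group count matrix."""
    counts = pd.DataFrame(
        {
            "a1": [100, 20, 0, 7],
            "a2": [110, 18, 1, 9],
            "b1": [95, 22, 0, 30],
            "b2": [105, 21, 2, 28],
        },
        index=pd.Index([f"g{i}" for i in range(4)], name="gene"),
    )
    design = pd.Series(
        ["A", "A", "B", "B"], index=pd.Index(counts.columns, name="sample"), name="group"
    )
    return tx.CountMatrix(counts, design)
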