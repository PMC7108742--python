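import numpy as np
import pytest

from markerpipe.io_meta import ExpressionMatrix, SampleMetadata
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_counts():
    """Deterministic 50-variable x 6-sample count matrix, two groups of 3."""
    gen = np.random.default_rng(11)
    counts = gen.poisson(60, size=(50, 6)).astype(float)
    X = ExpressionMatrix([f"g{i}" for i in range(50)], [f"s{j}" for j in range(6)],
                         counts, "seq")
    meta = SampleMetadata(
        pd.DataFrame({"group": ["a", "a", "a", "b", "b", "b"]},
                     index=pd.Index(X.sample_ids, name="sample_id")),
        "group",
    )
    return X, meta


def two_group_matrix(n_per_group=3, n_var=20, effect_rows=(), effect=2.0, sd=0.0,
                     seed=0):
    """Gaussian variables x samples grid with optional planted group shifts."""
    gen = np.random.default_rng(seed)
    n = 2 * n_per_group
    V = gen.normal(5.0, sd, size=(n_var, n)) if sd > 0 else np.full((n_var, n), 5.0)
    for r in effect_rows:
        V[r, n_per_group:] += effect
    X = ExpressionMatrix([f"v{i}" for i in range(n_var)],
                         [f"s{j}" for j in range(n)], V, "array")
    meta = SampleMetadata(
        pd.DataFrame({"group": ["a"] * n_per_group + ["b"] * n_per_group},
                     index=pd.Index(X.sample_ids, name="sample_id")),
        "group",
    )
    return X, meta
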