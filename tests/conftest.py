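import numpy as np
import pandas as pd
import pytest

from lnmacs import ExpressionMatrix, SimConfig, canonical_metadata, generate_counts


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    """3 genes x 2 samples, hand-written."""
    values = pd.DataFrame(
        [[10, 0], [3, 7], [0, 5]],
        index=pd.Index(["Actb", "Cd19", "Lyz2"], name="gene_id"),
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values, "counts")


@pytest.fixture
def meta16() -> pd.DataFrame:
    return canonical_metadata(pools=4)


@pytest.fixture(scope="session")
def small_sim():
    """One shared 300-gene synthetic dataset (counts + truth)."""
    cfg = SimConfig(n_genes=300, seed=42)
    counts, truth = generate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
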