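import numpy as np
import pandas as pd
import pytest

from coexdiv.expression import ExpressionDataset
from coexdiv.simulate import SyntheticExpressionConfig, generate_expression_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """One small two-condition dataset with 1 shared + 2 specific modules."""
    cfg = SyntheticExpressionConfig(
        n_genes=200,
        module_sizes=(40, 40, 40),
        shared_modules=1,
        specific_modules=2,
        seed=7,
    )
    datasets, truth = generate_expression_dataset(cfg)
    return cfg, datasets, truth


@pytest.fixture
def tiny_dataset():
    """A hand-made 4-gene x 4-sample dataset over two stages."""
    counts = pd.DataFrame(
        {
            "s1": [100, 200, 300, 400],
            "s2": [110, 190, 310, 390],
            "s3": [400, 200, 300, 100],
            "s4": [390, 210, 290, 110],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["A"] * 4,
            "stage": ["e1", "e1", "e2", "e2"],
            "period": ["prenatal"] * 4,
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(counts, samples)
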