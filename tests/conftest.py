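import numpy as np
import pandas as pd
import pytest

from dac import ClassLabel, ExpressionMatrix, train_wright_like_ensemble
from dac.io_formats import Level


@pytest.fixture(scope="session")
def wright_ensemble():
    """Default DAC ensemble trained on the Wright-like synthetic cohort."""
    ensemble, features, labels = train_wright_like_ensemble(seed=0)
    return ensemble, features, labels


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with distinct values."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.normal(8, 1, size=(3, 4)),
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df, level=Level.GENE)


@pytest.fixture
def separable_features():
    """Linearly separable 2-gene toy: ABC high in gene1, GCB high in gene2."""
    rng = np.random.default_rng(0)
    n = 10
    g1 = np.concatenate([rng.normal(3, 0.3, n), rng.normal(-3, 0.3, n)])
    g2 = np.concatenate([rng.normal(-3, 0.3, n), rng.normal(3, 0.3, n)])
    features = pd.DataFrame(
        {"gene1": g1, "gene2": g2}, index=[f"s{i}" for i in range(2 * n)]
    )
    labels = [ClassLabel.ABC] * n + [ClassLabel.GCB] * n
    return features, labels
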