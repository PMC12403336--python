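import numpy as np
import pandas as pd
import pytest

from lacrimark.preprocess import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """12 proteins x 10 samples, raw scale, ~20% missing."""
    values = np.power(2.0, rng.normal(20, 2, size=(12, 10)))
    mask = rng.random((12, 10)) < 0.2
    values[mask] = np.nan
    df = pd.DataFrame(
        values,
        index=[f"P{i:02d}" for i in range(12)],
        columns=[f"S{i:02d}" for i in range(10)],
    )
    return AbundanceMatrix.from_dataframe(df)


@pytest.fixture
def small_groups(small_matrix):
    labels = ["control"] * 5 + ["ALS"] * 5
    return pd.Series(labels, index=small_matrix.samples, name="group")
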