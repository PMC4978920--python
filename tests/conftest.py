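import numpy as np
import pandas as pd
import pytest

from p53screen import COLUMN_LABELS, ScreenMatrix


def make_matrix(values, genes=None, roles=None) -> ScreenMatrix:
    """Build a ScreenMatrix from an array-like of shape (n_genes, 6)."""
    arr = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"G{i:03d}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=list(COLUMN_LABELS))
    role_series = None
    if roles is not None:
        role_series = pd.Series(list(roles), index=genes)
    return ScreenMatrix(df, role_series)


@pytest.fixture
def rng():
    return np.random.default_rng(20160620)


@pytest.fixture
def small_matrix(rng):
    """12 library genes with lognormal expression around 1, no missing cells."""
    values = np.exp(rng.normal(0.0, 0.2, size=(12, 6)))
    return make_matrix(values)
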