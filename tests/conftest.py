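import numpy as np
import pandas as pd
import pytest

from txhet import ExpressionMatrix


def make_matrix(arr, gene_ids=None, cell_ids=None, meta=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cells = cell_ids or [f"c{j}" for j in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=genes, columns=cells)
    meta_df = pd.DataFrame(meta, index=cells) if meta is not None else None
    return ExpressionMatrix(values, meta_df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_matrix(rng):
    """Tie-free 10 x 5 matrix of uniform values."""
    return make_matrix(rng.random((10, 5)) * 100)
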