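import numpy as np
import pandas as pd
import pytest

from cafscape import CellMap, ExpressionMatrix


@pytest.fixture
def small_cell_map() -> CellMap:
    """Two slices: one with a line of reference cells, one with a pair."""
    rows = [
        ("c1", "s1", 0.0, 0.0, "F"),
        ("c2", "s1", 3.0, 0.0, "F"),
        ("c3", "s1", 6.0, 0.0, "F"),
        ("c4", "s1", 0.0, 4.0, "Q"),
        ("c5", "s2", 0.0, 0.0, "F"),
        ("c6", "s2", 1.0, 0.0, "Q"),
    ]
    return CellMap(
        pd.DataFrame(rows, columns=["cell_id", "slice_id", "x", "y", "cell_type"])
    )


@pytest.fixture
def random_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    vals = rng.gamma(2.0, 2.0, size=(20, 12))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i:03d}" for i in range(20)],
            columns=[f"c{i}" for i in range(12)],
        ),
        units="log",
    )


def make_counts_matrix(values: np.ndarray, genes=None, cells=None) -> ExpressionMatrix:
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), units="counts")
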