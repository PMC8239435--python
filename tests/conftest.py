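import numpy as np
import pandas as pd
import pytest

from togglefate.io import ExpressionMatrix, GeneSignature, normalize_counts
from togglefate.model import ToggleParams, find_fixed_points, stable_attractors


@pytest.fixture(scope="session")
def default_params() -> ToggleParams:
    return ToggleParams()


@pytest.fixture(scope="session")
def default_fixed_points(default_params):
    return find_fixed_points(default_params)


@pytest.fixture(scope="session")
def default_attractors(default_fixed_points):
    return stable_attractors(default_fixed_points)


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 cells × 2 genes of integer counts."""
    values = np.array([[1, 3], [0, 5], [2, 2]], dtype=float)
    return ExpressionMatrix(values, gene_ids=["IRF1", "IRF4"], cell_ids=["c1", "c2", "c3"])


@pytest.fixture
def two_cell_normalized() -> ExpressionMatrix:
    """2 cells, 1 gene with values (0, 2): per-gene z-scores are (−1, +1)."""
    return ExpressionMatrix(
        np.array([[0.0], [2.0]]),
        gene_ids=["IRF1"],
        cell_ids=["c1", "c2"],
        layer_tag="normalized",
    )


@pytest.fixture
def metadata_two_groups() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    del rng
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(1, 7)],
            "condition": ["unstimulated"] * 3 + ["TNF"] * 3,
        }
    )


def make_normalized(values, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{j}" for j in range(values.shape[1])]
    cell_ids = cell_ids or [f"c{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(values, gene_ids=gene_ids, cell_ids=cell_ids, layer_tag="normalized")


@pytest.fixture
def make_normalized_matrix():
    return make_normalized
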