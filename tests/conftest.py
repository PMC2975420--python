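"""Shared fixtures: the worked 5x9 example matrix and small helpers."""

import numpy as np
import pytest

from airnet.discretize import DiscreteMatrix
from airnet.io import ExpressionMatrix

EXAMPLE_SAMPLES = (
    "wt", "G1(-/-)", "G2(-/-)", "G3(-/-)", "G4(-/-)",
    "G5(-/-)", "G6(-/-)", "G7(-/-)", "G8(-/-)",
)

EXAMPLE_PRE = {
    "G1": [0.105, 0.034, 0.927, 0.088, 0.015, 0.049, 0.102, 0.105, 0.018],
    "G2": [0.877, 0.804, 0.000, 0.864, 0.870, 0.981, 0.837, 0.873, 0.797],
    "G3": [0.054, 0.000, 0.838, 0.000, 0.103, 0.000, 0.069, 0.000, 0.085],
    "G4": [0.386, 0.310, 0.611, 0.243, 0.083, 0.432, 0.440, 0.394, 0.364],
    "G5": [0.801, 0.808, 0.748, 0.903, 0.793, 0.000, 0.880, 0.741, 0.686],
}

# Published two-level discretization of the same matrix.  Row G4 is known to
# disagree with the SSE-optimal partition in one cell and is checked against
# the exact-solver oracle instead of these values.
EXAMPLE_POST = {
    "G1": [0, 0, 1, 0, 0, 0, 0, 0, 0],
    "G2": [1, 1, 0, 1, 1, 1, 1, 1, 1],
    "G3": [0, 0, 1, 0, 0, 0, 0, 0, 0],
    "G4": [1, 0, 1, 0, 0, 1, 1, 1, 1],
    "G5": [1, 1, 1, 1, 1, 0, 1, 1, 1],
}


@pytest.fixture
def example_expression() -> ExpressionMatrix:
    genes = tuple(EXAMPLE_PRE)
    values = np.array([EXAMPLE_PRE[g] for g in genes])
    return ExpressionMatrix(genes, EXAMPLE_SAMPLES, values)


@pytest.fixture
def example_expression_path(tmp_path, example_expression):
    from airnet.io import write_expression

    path = tmp_path / "example.tsv"
    write_expression(example_expression, path)
    return path


def make_discrete(rows: dict[str, list[int]], k: int = 2) -> DiscreteMatrix:
    genes = tuple(rows)
    n_samples = len(next(iter(rows.values())))
    samples = tuple(f"s{i}" for i in range(n_samples))
    return DiscreteMatrix(genes, samples, np.array([rows[g] for g in genes]), k)
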