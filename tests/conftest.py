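import numpy as np
import pandas as pd
import pytest

import benfordexpr as bx


@pytest.fixture(scope="session")
def default_data():
    """The reference six-group, 1,018-cell synthetic scenario."""
    return bx.generate(bx.default_scenario())


@pytest.fixture(scope="session")
def default_normalized(default_data):
    matrix, truth = default_data
    return bx.mrn_normalize(matrix), truth


@pytest.fixture(scope="session")
def small_data():
    """A small three-group scenario for fast pipeline tests."""
    spec = bx.SyntheticSpec(
        n_groups=3,
        cells_per_group=(40, 30, 30),
        group_names=("A", "B", "C"),
        n_background_genes=400,
        n_markers_per_group=30,
        n_de_genes_per_group=30,
        seed=7,
    )
    return bx.generate(spec)


@pytest.fixture(scope="session")
def small_normalized(small_data):
    matrix, truth = small_data
    return bx.mrn_normalize(matrix), truth


@pytest.fixture()
def tiny_matrix():
    """A 3-gene x 4-sample matrix with hand-checkable values."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 0.0],
            "s2": [2.0, 4.0, 0.0],
            "s3": [3.0, 6.0, 1.0],
            "s4": [4.0, 8.0, 0.0],
        },
        index=["g1", "g2", "g3"],
    )
    return bx.ExpressionMatrix(values=values, value_kind="raw_count")


def string_prefix_digit(x: float) -> int:
    """Independent oracle: first nonzero digit of the positional decimal
    rendering at 12 significant digits."""
    text = np.format_float_positional(x, precision=12, unique=False, fractional=False)
    for ch in text:
        if ch in "123456789":
            return int(ch)
    raise ValueError(f"no nonzero digit in {text!r}")
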