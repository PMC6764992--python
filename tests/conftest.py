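import numpy as np
import pandas as pd
import pytest

from wassermap.expression import ExpressionMatrix
from wassermap.network import from_edges


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    """Path A–B–C with unit strengths."""
    return from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def path6():
    genes = [f"n{i}" for i in range(1, 7)]
    return from_edges([(genes[i], genes[i + 1]) for i in range(5)])


@pytest.fixture
def triangle():
    return from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Hub H with three leaves."""
    return from_edges([("H", "L1"), ("H", "L2"), ("H", "L3")])


def make_matrix(values, genes=None, samples=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )


@pytest.fixture
def small_matrix():
    return make_matrix([[1, 2], [0, 5], [3, 3]], genes=["A", "B", "C"])


from .oracles import random_connected_network  # noqa: E402,F401  (shared helper)
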