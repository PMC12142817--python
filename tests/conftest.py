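import numpy as np
import pytest

from fminer import FormulaDataset, load_fixture
from fminer.rules import TransactionSet


@pytest.fixture(scope="session")
def classics() -> FormulaDataset:
    return load_fixture("classics")


@pytest.fixture(scope="session")
def lookup():
    return load_fixture("lookup")


@pytest.fixture(scope="session")
def attrs():
    return load_fixture("attributes")


@pytest.fixture
def toy_transactions() -> TransactionSet:
    """The 4-transaction worked example used across the rule tests."""
    return TransactionSet.from_lists(
        [{"A", "B"}, {"A", "B", "C"}, {"A", "C"}, {"B"}]
    )


def random_transactions(rng: np.random.Generator, n_items=None, n_trans=None):
    """Random transaction sets small enough for exhaustive oracles."""
    n_items = n_items or int(rng.integers(3, 11))
    n_trans = n_trans or int(rng.integers(2, 31))
    items = [f"i{k}" for k in range(n_items)]
    out = []
    for _ in range(n_trans):
        size = int(rng.integers(1, n_items + 1))
        out.append(frozenset(rng.choice(items, size=size, replace=False)))
    return out


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
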