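import numpy as np
import pytest

from wbfs import DiscreteTable, FeatureTable

# Worked 8-row fixture: C = f1 XOR f2 exactly; f3 agrees with C in 6/8 rows.
T8_ROWS = [
    (0, 0, 0, 0),
    (0, 1, 1, 1),
    (1, 0, 1, 1),
    (1, 1, 0, 0),
    (0, 0, 0, 0),
    (0, 1, 1, 1),
    (1, 0, 0, 1),
    (1, 1, 1, 0),
]


@pytest.fixture(scope="session")
def t8():
    """The worked fixture as a DiscreteTable (features f1, f2, f3; class C)."""
    a = np.array(T8_ROWS, dtype=np.int64)
    return DiscreteTable(a[:, :3], ["f1", "f2", "f3"], a[:, 3])


@pytest.fixture(scope="session")
def t8_columns():
    """The same fixture as plain lists for the brute-force oracles."""
    a = np.array(T8_ROWS)
    cols = {name: a[:, j].tolist() for j, name in enumerate(["f1", "f2", "f3"])}
    return cols, a[:, 3].tolist()


@pytest.fixture
def small_table():
    """A tiny continuous FeatureTable with one missing cell."""
    values = np.array(
        [
            [1.0, 10.0, 0.5],
            [2.0, np.nan, 0.7],
            [3.0, 30.0, 0.9],
            [4.0, 40.0, 1.1],
        ]
    )
    return FeatureTable(
        values, ["a", "b", "c"], np.array(["x", "y", "x", "y"], dtype=object)
    )


def random_discrete_table(rng, m=None, n=None, max_arity=3):
    """Random coded table for oracle-equivalence checks."""
    m = m or int(rng.integers(2, 9))
    n = n or int(rng.integers(10, 61))
    codes = rng.integers(0, rng.integers(2, max_arity + 1), size=(n, m))
    # ensure a non-constant class
    while True:
        c = rng.integers(0, 2, size=n)
        if len(np.unique(c)) >= 2:
            break
    return DiscreteTable(codes, [f"g{j}" for j in range(m)], c)
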