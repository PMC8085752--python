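import numpy as np
import pandas as pd
import pytest

from carex import CohortTable, ColumnSpec, FeatureSchema, MiningParams
from carex.items import Item

# Ten instances over two binary features; 2/10 positive. Small enough that
# every rule statistic can be counted by hand.
TOY_ROWS = [(1, 1, 1), (1, 0, 1), (1, 1, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0)] + [(0, 0, 0)] * 4


def toy_schema() -> FeatureSchema:
    return FeatureSchema.from_columns(
        [
            ColumnSpec("pid", "categorical", "id"),
            ColumnSpec("year", "continuous", "year"),
            ColumnSpec("A", "categorical"),
            ColumnSpec("B", "categorical"),
            ColumnSpec("outcome", "categorical", "outcome"),
        ]
    )


@pytest.fixture
def toy10() -> CohortTable:
    df = pd.DataFrame(
        [
            {"pid": str(i + 1), "year": 2012, "A": a, "B": b, "outcome": y}
            for i, (a, b, y) in enumerate(TOY_ROWS)
        ]
    )
    return CohortTable(df, toy_schema())


@pytest.fixture
def toy_catalog() -> list[Item]:
    return [Item("A", "1"), Item("B", "1"), Item("B", "0")]


@pytest.fixture
def toy_params() -> MiningParams:
    return MiningParams(min_commonality=0.5, min_confidence=0.4, max_lhs_items=2)


def random_cohort(rng: np.random.Generator, n: int, n_features: int) -> CohortTable:
    """Small random binary cohort for oracle-equivalence trials."""
    cols = [
        ColumnSpec("pid", "categorical", "id"),
        ColumnSpec("year", "continuous", "year"),
        *(ColumnSpec(f"f{i}", "categorical") for i in range(n_features)),
        ColumnSpec("outcome", "categorical", "outcome"),
    ]
    data = {
        "pid": [str(i) for i in range(n)],
        "year": np.full(n, 2012),
        "outcome": rng.integers(0, 2, size=n),
    }
    if data["outcome"].sum() == 0:
        data["outcome"][0] = 1
    for i in range(n_features):
        data[f"f{i}"] = rng.integers(0, 2, size=n)
    schema = FeatureSchema.from_columns(cols)
    return CohortTable(pd.DataFrame(data), schema)
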