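import numpy as np
import pandas as pd
import pytest

from annotlink import CATEGORICAL, NUMERIC, AnnotationInfo, CellTable
from annotlink.io import InfoEntry


def make_table(columns: dict, kinds: dict, ids=None) -> CellTable:
    """Small helper: build a CellTable from plain dicts; None means missing."""
    df = pd.DataFrame(
        {c: [np.nan if v is None else v for v in vals] for c, vals in columns.items()}
    )
    n = len(df)
    if ids is None:
        ids = [f"c{i}" for i in range(n)]
    return CellTable(ids, df, kinds)


def random_table(rng: np.random.Generator, n_max: int = 500) -> CellTable:
    """A random small table with two categorical and one numeric column,
    including missing values — the raw material for oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    ka = int(rng.integers(1, 6))
    kb = int(rng.integers(1, 6))
    a = [f"A{j}" for j in rng.integers(0, ka, size=n)]
    b = [f"B{j}" for j in rng.integers(0, kb, size=n)]
    a = [v if rng.random() > 0.1 else None for v in a]
    b = [v if rng.random() > 0.1 else None for v in b]
    x = rng.normal(size=n)
    x[rng.random(n) < 0.05] = np.nan
    return make_table(
        {"anno_a": a, "anno_b": b, "x": x},
        {"anno_a": CATEGORICAL, "anno_b": CATEGORICAL, "x": NUMERIC},
    )


@pytest.fixture
def simple_table() -> CellTable:
    """9 cells: class (Endo/Micro/Sst + 1 missing) and a numeric QC column."""
    return make_table(
        {
            "cls": ["Endo", "Endo", "Endo", "Micro", "Micro", "Sst", "Sst", "Sst", None],
            "n_genes": [500.0, 700.0, 900.0, 1500.0, 2000.0, 3000.0, 3500.0, None, 4000.0],
        },
        {"cls": CATEGORICAL, "n_genes": NUMERIC},
    )


@pytest.fixture
def simple_info() -> AnnotationInfo:
    return AnnotationInfo(
        [
            InfoEntry("cls", "Sst", order=0, direction="down"),
            InfoEntry("cls", "Endo", order=1, direction="unchanged"),
            InfoEntry("cls", "Micro", order=2, direction="up"),
        ]
    )
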