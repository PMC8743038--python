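import numpy as np
import pandas as pd
import pytest

from microdnds.pathways import PathwayMatrix
from microdnds.records import RECORD_COLUMNS


def make_table(rows):
    """Rows of (species, pair, gene, pathway, n_diff, n_opp, s_diff, s_opp)."""
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def make_matrix(values, species=None, pathways=None, support=None):
    values = np.asarray(values, dtype=float)
    n_sp, n_pw = values.shape
    species = species or [f"S{i+1:02d}" for i in range(n_sp)]
    pathways = pathways or [f"P{j+1:02d}" for j in range(n_pw)]
    if support is None:
        support = np.full(values.shape, 100, dtype=int)
    return PathwayMatrix(species, pathways, values, support)


@pytest.fixture
def toy_table():
    return make_table(
        [
            ("spA", "p1", "g1", "P1", 1, 100, 2, 50),
            ("spA", "p1", "g2", "P1", 3, 300, 2, 150),
            ("spA", "p1", "g3", "P2", 5, 200, 4, 100),
            ("spA", "p2", "g1", "P1", 2, 100, 3, 50),
            ("spB", "p1", "g1", "P1", 4, 100, 10, 50),
        ]
    )


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    rows = []
    for sp in ("spA", "spB", "spC"):
        for pair in ("p1", "p2"):
            for g in range(10):
                n_opp, s_opp = 500, 200
                rows.append(
                    (
                        sp,
                        pair,
                        f"g{g}",
                        f"P{g % 3}",
                        int(rng.integers(0, 30)),
                        n_opp,
                        int(rng.integers(1, 25)),
                        s_opp,
                    )
                )
    return make_table(rows)
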