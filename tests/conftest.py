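import logging

import pandas as pd
import pytest

from assemblyscope.community_data import CountTable, read_tree
from assemblyscope.simulate import simulate_tree

logging.getLogger("assemblyscope").setLevel(logging.ERROR)


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):0.5,(C:1,D:1):0.5); — 4 tips, patristic AB=2, AC=3."""
    return read_tree("((A:1,B:1):0.5,(C:1,D:1):0.5):0;")


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        [[5, 3, 0, 2], [0, 1, 4, 6], [1, 1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return CountTable(df)


@pytest.fixture
def toy_table():
    """3 samples x 4 taxa, totals <= 12 — the RC oracle fixture."""
    df = pd.DataFrame(
        [[3, 1, 0, 2], [0, 2, 4, 1], [1, 1, 1, 2]],
        index=["x", "y", "z"],
        columns=["A", "B", "C", "D"],
    )
    return CountTable(df)


@pytest.fixture(scope="session")
def yule_tree_100():
    return simulate_tree(100, seed=11)
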