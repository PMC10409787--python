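import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vitnet.io import AbundanceTable, PathwayCatalog


@pytest.fixture
def small_table() -> AbundanceTable:
    rng = np.random.default_rng(42)
    x = rng.random((6, 10)) + 0.01
    x = x / x.sum(axis=0, keepdims=True)
    return AbundanceTable(
        pd.DataFrame(
            x,
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(10)],
        )
    )


@pytest.fixture
def worked_graph() -> tuple[nx.Graph, dict[str, str]]:
    """Producer v with auxotrophic neighbors a1..a3 and producer p1; a1 is
    also adjacent to p1, a2/a3 only to v."""
    g = nx.Graph()
    g.add_edges_from([("v", "a1"), ("v", "a2"), ("v", "a3"), ("v", "p1"), ("a1", "p1")])
    roles = {
        "v": "producer",
        "p1": "producer",
        "a1": "auxotroph",
        "a2": "auxotroph",
        "a3": "auxotroph",
    }
    return g, roles


@pytest.fixture
def catalog() -> PathwayCatalog:
    return PathwayCatalog.default()


def make_fraction_table(arr: np.ndarray) -> AbundanceTable:
    n, m = arr.shape
    return AbundanceTable(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(m)],
        )
    )
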