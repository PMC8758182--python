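import networkx as nx
import numpy as np
import pandas as pd
import pytest

from disconet.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale world used by most generator tests."""
    return SyntheticConfig(rng_seed=1)


@pytest.fixture()
def mutation_table() -> pd.DataFrame:
    rows = [
        ("G1", 4, 100, "COSMIC", ""),
        ("G2", 3, 100, "COSMIC", ""),
        ("G3", 10, 100, "MUTFAM", "MF1"),
        ("G4", 8, 100, "MUTFAM", "MF1"),
        ("G5", 2, 100, "MUTFAM", "MF1"),
        ("G6", 1, 100, "MUTFAM", "MF1"),
        ("G7", 5, 100, "CGC", ""),
    ]
    return pd.DataFrame(
        rows, columns=["gene", "n_mutations", "n_samples_tested", "source", "mutfam_id"]
    )


@pytest.fixture()
def path3() -> nx.Graph:
    g = nx.Graph()
    g.add_edge("A", "B", weight=1.0)
    g.add_edge("B", "C", weight=1.0)
    return g


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.2) -> nx.Graph:
    """Connected Erdos-Renyi graph with string labels (retry until connected)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes()})
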