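import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bgcrank import simulate


@pytest.fixture
def species_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["h1", "h2", "t1", "t2", "l1"],
            "section": ["Harzianum", "Harzianum", "Trichoderma", "Trichoderma", "Longibrachiatum"],
            "strain": ["A", "B", "C", "", "E"],
        }
    )


@pytest.fixture
def count_table() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "species_id": ["h1", "h1", "h2", "t1", "l1"],
            "category": ["T1PKS", "NRPS", "T1PKS", "NRPS", "terpene"],
            "count": [4, 2, 0, 3, 5],
        }
    )
    frame["count"] = frame["count"].astype("int64")
    return frame


@pytest.fixture
def hit_table() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "species_id": ["h1", "h1", "h2", "t1", "t1", "l1"],
            "feature_name": ["clavaric acid", "enniatin", "clavaric acid",
                             "naphthopyrone", "squalestatin S1", "depudecin"],
            "match_percent": [100.0, 75.0, 74.9, 95.0, 50.9, 51.0],
            "annotation": [
                "hypothetical protein, partial",
                "non-ribosomal peptide synthetase",
                "",
                "Glycoside Hydrolase family 18 protein",
                "ABC transporter",
                "something unrecognized",
            ],
        }
    )
    frame["match_percent"] = frame["match_percent"].astype("float64")
    return frame


@pytest.fixture
def synthetic_bundle(tmp_path):
    """A planted-signal fixture bundle written to disk."""
    cfg = simulate.SimulationConfig(
        n_sections=4,
        species_per_section=5,
        categories=tuple(f"cat{i}" for i in range(10)),
        base_rate=2.0,
        planted_section="Harzianum",
        effect_multiplier=5.0,
        seed=20_001,
    )
    paths = simulate.simulate_bundle(cfg, tmp_path / "bundle")
    return cfg, dict(zip(("taxonomy", "counts", "hits"), paths))


def dense_pagerank(graph: nx.DiGraph, alpha: float) -> pd.Series:
    """Closed-form PageRank oracle: π = (1−α)/n · (I − α Mᵀ)⁻¹ 1.

    M is the row-stochastic transition matrix with dangling rows replaced
    by the uniform distribution. Independent of the package's power
    iteration.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        M[index[u], index[v]] = float(data.get("weight", 1.0))
    sums = M.sum(axis=1)
    for i in range(n):
        if sums[i] == 0:
            M[i] = 1.0 / n
        else:
            M[i] /= sums[i]
    pi = np.linalg.solve(np.eye(n) - alpha * M.T, np.full(n, (1 - alpha) / n))
    return pd.Series(pi, index=pd.Index(nodes, name="node"))


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.DiGraph:
    """Small random weighted digraph (may contain dangling nodes)."""
    n = int(rng.integers(2, max_nodes + 1))
    graph = nx.DiGraph()
    graph.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                graph.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.1, 5.0)))
    return graph
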