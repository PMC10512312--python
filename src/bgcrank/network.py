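"""Weighted directed bipartite graph construction and PageRank centrality.

The section × category average matrix becomes a directed bipartite graph:
section nodes point at feature nodes, each edge weighted by the section's
average observation count for that feature. Two families of centrality
are computed on it:

* **strength** — the plain weighted degree: out-strength for sections
  (total average signal a section emits), in-strength for features
  (total average signal a feature accumulates);
* **broadcasting / receiving PageRank** — the stationary distribution of
  a damped, weight-proportional random walk. Receiving scores come from
  the graph as built (mass flows from sections into features);
  broadcasting scores are PageRank on the edge-reversed graph, so a
  section is influential when it feeds the features that themselves rank
  highly. Scores are min-max normalized separately within the section
  and feature node classes, mirroring how each panel of a paired bar
  chart spans [0, 1].

The walk follows out-edges with probability proportional to edge weight,
teleports uniformly with probability ``1 − damping``, and redistributes
the mass of dangling nodes (feature nodes, which have no out-edges in
this bipartite layout) uniformly over all nodes — the standard completion
without which the bipartite chain would absorb all mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .aggregate import SectionMatrix
from .errors import ConfigurationError, ConvergenceError

logger = logging.getLogger(__name__)

SECTION_CLASS = "section"
FEATURE_CLASS = "feature"


@dataclass(frozen=True)
class PageRankParams:
    """Power-iteration parameters for the damped random walk.

    ``damping`` is the probability of following an edge rather than
    teleporting (canonically 0.85); iteration stops when the L1 change of
    the score vector drops below ``tolerance``.
    """

    damping: float = 0.85
    tolerance: float = 1e-10
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ConfigurationError(f"damping must be in (0, 1), got {self.damping}")
        if self.tolerance <= 0:
            raise ConfigurationError(f"tolerance must be > 0, got {self.tolerance}")
        if self.max_iterations < 1:
            raise ConfigurationError(
                f"max_iterations must be ≥ 1, got {self.max_iterations}"
            )


def build_graph(
    matrix: SectionMatrix,
    *,
    include_empty_features: bool = False,
    binarize: bool = False,
) -> nx.DiGraph:
    """Turn a section × category matrix into the bipartite digraph.

    One node per section and per category with at least one positive
    cell; an edge ``section → category`` exists iff the cell is positive,
    carrying the cell value as weight (or 1.0 when ``binarize``).
    All-zero categories are dropped unless ``include_empty_features``.
    """
    values = matrix.values
    if values.size == 0 or not (values.to_numpy() > 0).any():
        raise ConfigurationError("section matrix has no positive cells; empty graph")
    overlap = set(values.index) & set(values.columns)
    if overlap:
        raise ConfigurationError(f"labels shared between sections and features: {sorted(overlap)}")
    graph = nx.DiGraph()
    for section in values.index:
        graph.add_node(str(section), node_class=SECTION_CLASS)
    for category in values.columns:
        if include_empty_features or (values[category].to_numpy() > 0).any():
            graph.add_node(str(category), node_class=FEATURE_CLASS)
    for section in values.index:
        for category in values.columns:
            weight = float(values.at[section, category])
            if weight > 0:
                graph.add_edge(
                    str(section), str(category),
                    weight=1.0 if binarize else weight,
                )
    return graph


def node_strength(graph: nx.DiGraph) -> pd.DataFrame:
    """Weighted out- and in-degree per node."""
    nodes = list(graph.nodes)
    return pd.DataFrame(
        {
            "out_strength": [graph.out_degree(v, weight="weight") for v in nodes],
            "in_strength": [graph.in_degree(v, weight="weight") for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
        dtype=float,
    )


def _transition_matrix(graph: nx.DiGraph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition matrix and dangling-row indicator."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        P[index[u], index[v]] = float(data.get("weight", 1.0))
    row_sums = P.sum(axis=1)
    dangling = row_sums == 0.0
    P[~dangling] /= row_sums[~dangling, None]
    return P, dangling


def pagerank(
    graph: nx.DiGraph, params: PageRankParams | None = None
) -> tuple[pd.Series, dict]:
    """Stationary vector of the damped weight-proportional random walk.

    Power iteration: ``π ← α (πᵀP + (π·d)/n · 1) + (1−α)/n``, where ``P``
    is row-stochastic over out-edges, ``d`` flags dangling nodes whose
    mass is spread uniformly, and ``α`` is the damping factor. Returns
    the score Series (summing to 1) and solver metadata.
    """
    params = params or PageRankParams()
    if graph.number_of_nodes() == 0:
        raise ConfigurationError("cannot rank an empty graph")
    nodes = list(graph.nodes)
    n = len(nodes)
    P, dangling = _transition_matrix(graph, nodes)
    alpha = params.damping
    pi = np.full(n, 1.0 / n)
    teleport = (1.0 - alpha) / n
    residual = np.inf
    for iteration in range(1, params.max_iterations + 1):
        dangling_mass = pi[dangling].sum()
        new = alpha * (pi @ P + dangling_mass / n) + teleport
        residual = float(np.abs(new - pi).sum())
        pi = new
        if residual < params.tolerance:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {params.max_iterations} iterations "
            f"(L1 residual {residual:.3e})",
            residual=residual,
            iterations=params.max_iterations,
        )
    scores = pd.Series(pi, index=pd.Index(nodes, name="node"), name="pagerank")
    return scores, {"iterations": iteration, "residual": residual}


def minmax_normalize(scores: pd.Series, subset: list[str] | None = None) -> pd.Series:
    """Affine map of a score subset onto [0, 1].

    A degenerate range (all scores equal) maps everything to 0 and logs a
    warning — no variation carries no ranking signal.
    """
    values = scores if subset is None else scores.loc[list(subset)]
    if values.empty:
        raise ConfigurationError("cannot normalize an empty subset")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        logger.warning(
            "degenerate min-max range (all scores equal %.6g); mapping subset to 0", lo
        )
        return pd.Series(0.0, index=values.index)
    return (values - lo) / (hi - lo)


@dataclass
class CentralityResult:
    """Per-node strength and raw + normalized broadcast/receive PageRank.

    ``frame`` columns: node_class, out_strength, in_strength,
    broadcast_raw, receive_raw, broadcast_norm, receive_norm.
    Normalization is per node class (sections among sections, features
    among features).
    """

    frame: pd.DataFrame
    params: PageRankParams
    solver_info: dict = field(default_factory=dict)

    def nodes_of_class(self, node_class: str) -> pd.DataFrame:
        return self.frame[self.frame["node_class"] == node_class]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="node", lineterminator="\n")


def broadcast_receive(
    graph: nx.DiGraph, params: PageRankParams | None = None
) -> CentralityResult:
    """Compute strengths and broadcasting/receiving PageRank for a graph.

    Receiving scores are PageRank on the graph as given; broadcasting
    scores are PageRank on the same graph with every edge reversed
    (weights kept), so the two are exact duals. Each score vector is then
    min-max normalized within the section-node and feature-node subsets
    separately.
    """
    params = params or PageRankParams()
    receive, info_r = pagerank(graph, params)
    broadcast, info_b = pagerank(graph.reverse(copy=True), params)
    strengths = node_strength(graph)
    classes = pd.Series(
        {v: graph.nodes[v].get("node_class", FEATURE_CLASS) for v in graph.nodes},
        name="node_class",
    )
    frame = strengths.copy()
    frame.insert(0, "node_class", classes)
    frame["broadcast_raw"] = broadcast
    frame["receive_raw"] = receive
    frame["broadcast_norm"] = np.nan
    frame["receive_norm"] = np.nan
    for node_class in frame["node_class"].unique():
        members = frame.index[frame["node_class"] == node_class].tolist()
        frame.loc[members, "broadcast_norm"] = minmax_normalize(broadcast, members)
        frame.loc[members, "receive_norm"] = minmax_normalize(receive, members)
    return CentralityResult(
        frame=frame,
        params=params,
        solver_info={"receive": info_r, "broadcast": info_b},
    )


def write_edge_list(graph: nx.DiGraph, path) -> None:
    """Edge-list TSV: source, target, weight."""
    rows = [
        {"source": u, "target": v, "weight": data["weight"]}
        for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
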