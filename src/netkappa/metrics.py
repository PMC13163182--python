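"""Nodal and global topology metrics for binarized brain graphs.

Nodal metrics: degree centrality (normalized by the maximum degree in the
network, not by N-1), local clustering coefficient, closeness centrality,
plus weighted-degree variants computed directly from the correlation matrix.
Global metrics: global efficiency, average clustering (mean of the nodal
values), average shortest path length, modularity of a greedy community
partition, and the mean geodesic distance between nodes in different
communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import BrainGraph, build_graph, mst_edges

__all__ = [
    "GlobalMetricRecord",
    "degree_centrality",
    "clustering_coefficient",
    "closeness_centrality",
    "weighted_degree",
    "global_metrics",
    "nodal_metric_table",
    "NODAL_METRICS",
]


def _as_series(d: dict, node_ids: list[str]) -> pd.Series:
    return pd.Series([d[n] for n in node_ids], index=pd.Index(node_ids, name="node_id"))


def degree_centrality(g: BrainGraph, max_normalized: bool = True) -> pd.Series:
    """Degree divided by the highest degree in the network.

    ``max_normalized=False`` restores the textbook (N-1) normalization.
    """
    deg = dict(g.graph.degree())
    denom = max(deg.values()) if max_normalized else g.n_nodes - 1
    return _as_series({n: k / denom for n, k in deg.items()}, g.node_ids)


def clustering_coefficient(g: BrainGraph) -> pd.Series:
    """Local clustering: closed triangles over possible neighbor pairs."""
    return _as_series(nx.clustering(g.graph), g.node_ids)


def closeness_centrality(g: BrainGraph) -> pd.Series:
    """Closeness ``(N-1) / sum_j d(i, j)`` on a connected graph."""
    return _as_series(nx.closeness_centrality(g.graph), g.node_ids)


def weighted_degree(cm, edge_budget: int | None = None, mode: str = "all_pairs") -> pd.Series:
    """Sum of |r| over incident retained pairs.

    mode 'all_pairs' sums every pair; 'with_mst' sums over the MST-anchored
    ``edge_budget``-edge graph; 'without_mst' sums over the ``edge_budget``
    strongest pairs with no spanning-tree anchoring.
    """
    values = np.abs(np.asarray(getattr(cm, "values", cm), dtype=float))
    node_ids = list(getattr(cm, "region_ids", [str(i) for i in range(len(values))]))
    n = len(node_ids)
    np.fill_diagonal(values, 0.0)
    if mode == "all_pairs":
        return pd.Series(values.sum(axis=1), index=pd.Index(node_ids, name="node_id"))
    if edge_budget is None:
        raise ValueError(f"mode {mode!r} requires edge_budget")
    if mode == "with_mst":
        bg = build_graph(cm, edge_budget)
        edges = set(map(lambda e: tuple(sorted(e)), bg.graph.edges))
    elif mode == "without_mst":
        iu, ju = np.triu_indices(n, k=1)
        order = np.lexsort((ju, iu, -values[iu, ju]))[:edge_budget]
        edges = {tuple(sorted((node_ids[int(iu[k])], node_ids[int(ju[k])]))) for k in order}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    index = {rid: k for k, rid in enumerate(node_ids)}
    out = dict.fromkeys(node_ids, 0.0)
    for u, v in edges:
        w = values[index[u], index[v]]
        out[u] += w
        out[v] += w
    return _as_series(out, node_ids)


@dataclass
class GlobalMetricRecord:
    """Single-number network summaries for one scan."""

    subject_id: str | None
    condition: str | None
    global_efficiency: float
    average_clustering: float
    average_path_length: float
    modularity: float
    avg_between_community_distance: float  # NaN when a single community
    community_partition: list[frozenset]

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "global_efficiency": self.global_efficiency,
            "average_clustering": self.average_clustering,
            "average_path_length": self.average_path_length,
            "modularity": self.modularity,
            "avg_between_community_distance": self.avg_between_community_distance,
            "n_communities": len(self.community_partition),
        }


def _communities(g: nx.Graph, algorithm: str, seed: int | None):
    if algorithm == "greedy":
        return [frozenset(c) for c in nx.community.greedy_modularity_communities(g)]
    if algorithm == "louvain":
        return [frozenset(c) for c in nx.community.louvain_communities(g, seed=seed)]
    raise ValueError(f"unknown community algorithm {algorithm!r}")


def global_metrics(
    g: BrainGraph, algorithm: str = "greedy", seed: int | None = 0
) -> GlobalMetricRecord:
    """Global efficiency, mean clustering, mean path length, modularity and
    mean between-community geodesic distance of a connected graph.

    A single-community partition leaves the between-community distance
    undefined; it is recorded as NaN, never as zero.
    """
    graph = g.graph
    if not nx.is_connected(graph):
        raise ValueError("global metrics require a connected graph")
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    nodes = g.node_ids
    dists = np.array([[spl[u][v] for v in nodes] for u in nodes], dtype=float)
    iu = np.triu_indices(len(nodes), k=1)
    pair_d = dists[iu]
    efficiency = float(np.mean(1.0 / pair_d))
    path_length = float(np.mean(pair_d))
    avg_clust = float(clustering_coefficient(g).mean())

    comms = _communities(graph, algorithm, seed)
    mod = float(nx.community.modularity(graph, comms))
    label = {}
    for c_idx, c in enumerate(comms):
        for n in c:
            label[n] = c_idx
    lab = np.array([label[n] for n in nodes])
    between = lab[iu[0]] != lab[iu[1]]
    between_d = float(np.mean(pair_d[between])) if between.any() else float("nan")

    return GlobalMetricRecord(
        subject_id=g.subject_id,
        condition=g.condition,
        global_efficiency=efficiency,
        average_clustering=avg_clust,
        average_path_length=path_length,
        modularity=mod,
        avg_between_community_distance=between_d,
        community_partition=comms,
    )


NODAL_METRICS = {
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "clustering": clustering_coefficient,
}


def nodal_metric_table(graphs: dict[tuple[str, str], BrainGraph]) -> pd.DataFrame:
    """Tidy nodal metric table across a cohort of graphs.

    ``graphs`` maps (subject_id, condition) to a graph; the result has
    columns subject_id, condition, node_id, metric, value.
    """
    rows = []
    for (subject_id, condition), g in graphs.items():
        for metric, fn in NODAL_METRICS.items():
            s = fn(g)
            for node_id, value in s.items():
                rows.append((subject_id, condition, node_id, metric, float(value)))
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "node_id", "metric", "value"]
    )
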