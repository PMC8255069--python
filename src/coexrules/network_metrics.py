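"""Gene-network construction and centrality analysis.

Builds a simple undirected graph from a TOM or adjacency matrix by
thresholding edge weights, and computes the four centrality measures
used to rank hub genes -- degree, betweenness, closeness and the local
clustering coefficient -- plus graph density and a degree filter.

Shortest-path-based measures use unweighted (hop-count) paths by
default, matching the convention of common network-analyzer tools;
pass ``weighted=True`` to use ``1 / weight`` edge lengths instead.
Betweenness is normalized by ``(n-1)(n-2)/2``; closeness is the simple
per-component variant ``(n_reachable - 1) / sum of distances`` (an
isolated node scores 0).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "degree",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "density",
    "filter_by_degree",
    "centrality_table",
    "hub_table",
]


def build_network(
    weights: pd.DataFrame,
    edge_threshold: float,
    node_subset=None,
    categories: dict[str, str] | None = None,
) -> nx.Graph:
    """Threshold a symmetric weight matrix into an undirected graph.

    An edge (i, j) is included iff ``weight >= edge_threshold`` (with
    0 < threshold <= 1) and both endpoints are in ``node_subset`` (all
    genes if omitted). Weights are kept as edge attributes; every
    subset gene becomes a node even if isolated. Optional
    ``categories`` (gene -> chemosensory / non_chemosensory /
    unannotated) are stored as node attributes.
    """
    if not 0 < edge_threshold <= 1:
        raise ValueError("edge_threshold must lie in (0, 1]")
    if not isinstance(weights, pd.DataFrame):
        weights = pd.DataFrame(np.asarray(weights, dtype=float))
    if node_subset is not None:
        nodes = [g for g in weights.index if g in set(node_subset)]
        weights = weights.loc[nodes, nodes]
    graph = nx.Graph()
    graph.add_nodes_from(weights.index)
    values = weights.to_numpy(dtype=float)
    ii, jj = np.where(np.triu(values >= edge_threshold, k=1))
    labels = weights.index
    graph.add_weighted_edges_from(
        (labels[i], labels[j], float(values[i, j])) for i, j in zip(ii, jj)
    )
    if categories:
        nx.set_node_attributes(
            graph, {n: categories[n] for n in graph.nodes if n in categories}, "category"
        )
    return graph


def _distance_kwarg(graph: nx.Graph, weighted: bool) -> dict:
    if not weighted:
        return {}
    for _, _, data in graph.edges(data=True):
        data["distance"] = 1.0 / data.get("weight", 1.0)
    return {"weight": "distance", "distance": "distance"}


def degree(net: nx.Graph) -> pd.Series:
    """Number of incident edges per node (sums to 2|E|)."""
    return pd.Series(dict(net.degree()), dtype=int, name="degree").reindex(net.nodes)


def betweenness(net: nx.Graph, weighted: bool = False) -> pd.Series:
    """Fraction of pairwise shortest paths through each node.

    Normalized by ``(n-1)(n-2)/2``; endpoints are excluded.
    """
    kw = {}
    if weighted:
        _distance_kwarg(net, True)
        kw["weight"] = "distance"
    values = nx.betweenness_centrality(net, normalized=True, **kw)
    return pd.Series(values, dtype=float, name="betweenness").reindex(net.nodes)


def closeness(net: nx.Graph, weighted: bool = False) -> pd.Series:
    """Per-component closeness ``(n_reachable - 1) / sum of distances``."""
    kw = {}
    if weighted:
        _distance_kwarg(net, True)
        kw["distance"] = "distance"
    values = nx.closeness_centrality(net, wf_improved=False, **kw)
    return pd.Series(values, dtype=float, name="closeness").reindex(net.nodes)


def clustering_coefficient(net: nx.Graph) -> pd.Series:
    """Edge density of each node's neighborhood (0 when degree < 2)."""
    values = nx.clustering(net)
    return pd.Series(values, dtype=float, name="clustering_coefficient").reindex(net.nodes)


def density(net: nx.Graph) -> float:
    """Graph density ``2|E| / (n(n-1))``; requires at least two nodes."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density requires >= 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def filter_by_degree(net: nx.Graph, min_degree: int = 5, iterative: bool = False) -> nx.Graph:
    """Drop nodes with degree below ``min_degree``.

    By default degrees are computed once on the input graph and the
    induced subgraph on the surviving nodes is returned (single pass);
    ``iterative=True`` instead peels nodes repeatedly (k-core).
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    if iterative:
        return nx.k_core(net, k=min_degree).copy()
    keep = [n for n, d in net.degree() if d >= min_degree]
    return net.subgraph(keep).copy()


def centrality_table(net: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Per-node table of the four centrality measures (plus category)."""
    table = pd.DataFrame(
        {
            "degree": degree(net),
            "betweenness": betweenness(net, weighted=weighted),
            "closeness": closeness(net, weighted=weighted),
            "clustering_coefficient": clustering_coefficient(net),
        }
    )
    cats = nx.get_node_attributes(net, "category")
    if cats:
        table["category"] = pd.Series(cats).reindex(table.index)
    table.index.name = "gene_id"
    return table


def hub_table(ct: pd.DataFrame, min_degree: int = 8) -> pd.DataFrame:
    """Hub genes: degree >= ``min_degree``, ranked deterministically.

    Sorted by degree (descending), then betweenness (descending), then
    gene id (ascending).
    """
    hubs = ct[ct["degree"] >= min_degree]
    hubs = hubs.sort_index(kind="stable").sort_values(
        ["degree", "betweenness"], ascending=[False, False], kind="stable"
    )
    return hubs
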