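"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from itertools import chain, combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexrules import CountMatrix, SimConfig, generate_counts


# ------------------------------------------------------------ oracles

def brute_force_itemsets(transactions, min_support) -> dict[frozenset, Fraction]:
    """Exhaustive enumeration of every frequent itemset with its support."""
    transactions = [frozenset(t) for t in transactions]
    n = len(transactions)
    items = sorted(set(chain.from_iterable(transactions)))
    need = Fraction(min_support).limit_denominator(10**6)
    out = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            supp = Fraction(sum(1 for t in transactions if s <= t), n)
            if supp >= need:
                out[s] = supp
    return out


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values straight from the definition.

    padj_i = min over all j with rank(p_j) >= rank(p_i) of
    min(1, m * p_j / rank(p_j)).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if ranks[j] >= ranks[i]
        ]
        out[i] = min(candidates)
    return out


def brute_force_shortest_path_stats(graph: nx.Graph):
    """Betweenness / closeness from plain BFS path counting.

    Independent of networkx's centrality code: BFS distances per
    source, shortest-path counts by dynamic programming over the
    distance layers, and pair-by-pair accumulation of the fraction of
    shortest s-t paths through each interior node.
    """
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(graph, v)
        for u, d in lengths.items():
            dist[index[v], index[u]] = d

    # path counts sigma[s, t]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(
            [t for t in range(n) if np.isfinite(dist[s, t])], key=lambda t: dist[s, t]
        )
        for t in order:
            if dist[s, t] == 0:
                sigma[s, t] = 1
                continue
            sigma[s, t] = sum(
                sigma[s, u]
                for u in range(n)
                if dist[s, u] == dist[s, t] - 1 and graph.has_edge(nodes[u], nodes[t])
            )

    bet = dict.fromkeys(nodes, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bet[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2
    betweenness = {v: (b / norm if norm > 0 else 0.0) for v, b in bet.items()}

    closeness = {}
    for s in range(n):
        reach = [t for t in range(n) if t != s and np.isfinite(dist[s, t])]
        total = sum(dist[s, t] for t in reach)
        closeness[nodes[s]] = len(reach) / total if total > 0 else 0.0

    clustering = {}
    for v in nodes:
        nbrs = list(graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b)
        )
        clustering[v] = links / (k * (k - 1) / 2)
    return betweenness, closeness, clustering


# ----------------------------------------------------------- fixtures

@pytest.fixture
def tiny_counts() -> CountMatrix:
    """A hand-written 4-gene x 6-sample count matrix (2 treatments x 3)."""
    counts = pd.DataFrame(
        {
            "attractant_1": [100, 12, 0, 40],
            "attractant_2": [110, 15, 1, 44],
            "attractant_3": [90, 11, 0, 36],
            "control_1": [95, 3, 0, 42],
            "control_2": [105, 2, 1, 38],
            "control_3": [100, 4, 0, 40],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "treatment": ["attractant"] * 3 + ["control"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def modular_dataset():
    """Simulated counts with four planted 50-gene modules (20 samples)."""
    config = SimConfig(
        n_genes=500,
        n_modules=4,
        module_size=50,
        n_samples=20,
        within_module_cor=0.7,
        de_gene_frac=0.0,
        seed=1,
    )
    return generate_counts(config)
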