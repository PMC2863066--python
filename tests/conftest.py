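"""Shared fixtures: small labeled graphs, random instances, the engineered
5-gene expression matrix, and random neighborhood-pair generators."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netortho.network_model import LabeledGraph, Neighborhood, khop_neighborhood


def make_graph(edges, nodes=(), weighted=False, species="test") -> LabeledGraph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if weighted:
        g.add_weighted_edges_from(edges)
    else:
        g.add_edges_from(edges)
    return LabeledGraph(graph=g, species=species, weighted=weighted)


def random_labeled_graph(
    rng: np.random.Generator, n_max: int = 8, weighted: bool = False, n_min: int = 2
) -> LabeledGraph:
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.2, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    lg = LabeledGraph(graph=g, weighted=weighted)
    if weighted:
        for u, v, data in g.edges(data=True):
            data["weight"] = float(rng.uniform(0.05, 1.0))
    return lg


def random_neighborhood_pair(
    rng: np.random.Generator, n_max: int = 8, weighted: bool = False
) -> tuple[Neighborhood, Neighborhood, dict]:
    """Two random k-hop neighborhoods plus a random pre-normalized homology map."""
    g1 = random_labeled_graph(rng, n_max, weighted)
    g2 = random_labeled_graph(rng, n_max, weighted)
    g2.graph = nx.relabel_nodes(g2.graph, {v: v + "'" for v in g2.graph.nodes})
    k = int(rng.integers(1, 3))
    C = khop_neighborhood(g1, sorted(g1.nodes)[0], k)
    Z = khop_neighborhood(g2, sorted(g2.nodes)[0], k)
    hom = {
        (u, v): float(rng.uniform(0.1, 1.0))
        for u in sorted(C.nodes)
        for v in sorted(Z.nodes)
        if rng.random() < 0.4
    }
    return C, Z, hom


@pytest.fixture
def path_abc() -> LabeledGraph:
    return make_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star5() -> LabeledGraph:
    """Star with center and 4 leaves."""
    return make_graph([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def cycle4() -> LabeledGraph:
    return make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    """5 genes x 8 tissues engineered so exactly 3 pairs reach |rho| >= 0.8:
    gA-gB (rho = 1), gA-gC and gB-gC (rho = -0.905); gA-gD sits at 0.5 and gE
    is near-noise against everything."""
    return pd.DataFrame(
        {
            "gA": [1, 2, 3, 4, 5, 6, 7, 8],
            "gB": [1, 4, 9, 16, 25, 36, 49, 64],
            "gC": [6, 7, 8, 5, 4, 3, 2, 1],
            "gD": [1, 2, 4, 6, 7, 8, 5, 3],
            "gE": [1, 7, 3, 8, 5, 2, 6, 4],
        },
        index=[f"t{i}" for i in range(8)],
    ).T
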