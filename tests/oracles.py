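"""Independent brute-force oracles used to verify the implementation.

Every oracle here recomputes a quantity by direct enumeration or naive linear
algebra, deliberately avoiding the code paths it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from netortho.network_model import LabeledGraph, Neighborhood


def dijkstra_all_pairs(g: LabeledGraph, weight_mode: str) -> dict:
    """Per-source Dijkstra distances with edge length 1 or 1 - weight."""
    h = g.graph.copy()
    for u, v, data in h.edges(data=True):
        data["length"] = 1.0 if weight_mode == "unit" else 1.0 - data.get("weight", 1.0)
    return dict(nx.all_pairs_dijkstra_path_length(h, weight="length"))


def sp_kernel_double_sum(
    C: Neighborhood, Z: Neighborhood, hom: dict, weight_mode: str, epsilon: float
) -> float:
    """Exhaustive double sum over all ordered vertex pairs of both subgraphs."""
    dc = dijkstra_all_pairs(C.subgraph, weight_mode)
    dz = dijkstra_all_pairs(Z.subgraph, weight_mode)
    total = 0.0
    for u, v in itertools.permutations(sorted(C.nodes), 2):
        if v not in dc[u]:
            continue
        for up, vp in itertools.permutations(sorted(Z.nodes), 2):
            if vp not in dz[up]:
                continue
            h = hom.get((u, up), 0.0) * hom.get((v, vp), 0.0)
            if h and abs(dc[u][v] - dz[up][vp]) <= epsilon:
                total += h
    return total


def rw_kernel_full_matrix(
    C: Neighborhood,
    Z: Neighborhood,
    hom: dict,
    lam: float,
    weight_mode: str = "unit",
    terms: int = 60,
) -> float:
    """Truncated Neumann series sum_i lam^i p K^i q on the full nm x nm matrix."""
    cn = sorted(C.nodes)
    zn = sorted(Z.nodes)
    n, m = len(cn), len(zn)
    pairs = [(u, up) for u in cn for up in zn]
    K = np.zeros((n * m, n * m))
    gc, gz = C.subgraph, Z.subgraph
    for i, (u, up) in enumerate(pairs):
        for j, (v, vp) in enumerate(pairs):
            if gc.graph.has_edge(u, v) and gz.graph.has_edge(up, vp):
                wc = gc.weight(u, v) if weight_mode != "unit" else 1.0
                wz = gz.weight(up, vp) if weight_mode != "unit" else 1.0
                K[i, j] = wc * wz * hom.get((u, up), 0.0) * hom.get((v, vp), 0.0)
    q = np.ones(n * m)
    total = 0.0
    vec = q.copy()
    for _ in range(terms + 1):
        total += vec.sum()
        vec = lam * (K @ vec)
    return float(total)


def betweenness_by_path_enumeration(g: LabeledGraph, weight_mode: str = "unit") -> dict:
    """Count shortest paths explicitly for every unordered (s, t) pair."""
    h = g.graph.copy()
    attr = None
    if weight_mode != "unit":
        for u, v, data in h.edges(data=True):
            data["length"] = 1.0 - data.get("weight", 1.0)
        attr = "length"
    scores = {v: 0.0 for v in h.nodes}
    for s, t in itertools.combinations(sorted(h.nodes), 2):
        if not nx.has_path(h, s, t):
            continue
        paths = list(nx.all_shortest_paths(h, s, t, weight=attr))
        for v in h.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores


def rbh_by_argmax(scores: dict) -> set:
    """Reciprocal argmax with lexicographic tie-breaking, by direct search."""
    a_side = sorted({a for a, _ in scores})
    b_side = sorted({b for _, b in scores})

    def best_for_a(a):
        cand = {b: s for (x, b), s in scores.items() if x == a}
        top = max(cand.values())
        return min(b for b, s in cand.items() if s == top)

    def best_for_b(b):
        cand = {a: s for (a, y), s in scores.items() if y == b}
        top = max(cand.values())
        return min(a for a, s in cand.items() if s == top)

    return {
        (a, best_for_a(a))
        for a in a_side
        if best_for_b(best_for_a(a)) == a
    }


def auc_by_pair_counting(scores, labels) -> float:
    """AUC in percent by exhaustive positive/negative pair comparison."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


def hits_by_eigensolver(g: LabeledGraph) -> dict:
    """Hub + authority from the dominant eigenvector of A A^T (dense eigh)."""
    nodes = sorted(g.graph.nodes)
    A = nx.to_numpy_array(g.graph, nodelist=nodes, weight=None)
    w, V = np.linalg.eigh(A @ A.T)
    v = V[:, np.argmax(w)]
    v = np.abs(v) / np.linalg.norm(v)
    return {node: 2.0 * float(v[i]) for i, node in enumerate(nodes)}
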