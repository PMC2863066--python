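"""Homology-weighted shortest-path and random-walk graph kernels.

Both kernels compare the k-hop neighborhoods C and Z of a candidate ortholog
pair, coupling vertices across the two subgraphs through their normalized
sequence-homology scores hom(u, u') in [0, 1].

Shortest-path kernel
    k_sp(C, Z) = sum over ordered vertex pairs (u, v) in C^2 and (u', v') in
    Z^2 (u != v, u' != v', both pairs connected) of
    hom(u, u') * hom(v, v') * kappa_len(d_C(u, v), d_Z(u', v')),
    where kappa_len(d, d') = 1 iff |d - d'| <= epsilon.  On unweighted graphs
    hop distances are integers and epsilon = 0 (exact length match); on
    correlation-weighted graphs edges have length 1 - |rho| and epsilon
    defaults to 0.05.

Random-walk kernel
    k_rw(C, Z) = p (I - lambda * K)^{-1} q, where K is the nm x nm
    homology-weighted Kronecker-product matrix
    K[(u,u'), (v,v')] = w_C(u, v) * w_Z(u', v') * hom(u, u') * hom(v, v')
    (w = adjacency, or the correlation weight on weighted graphs), p and q
    are all-ones vectors summing the inverse's entries, and lambda (default
    0.01) damps long walks.  The series converges iff
    lambda * spectral_radius(K) < 1.

Because K vanishes on every row and column whose vertex pair has zero
homology, it is block-diagonal: the identity block contributes nm - |S| and
the computation reduces to the |S| x |S| homology-supported block (S = cross
pairs with hom > 0).  This is an exact rewrite of the naive nm x nm inverse,
which tests verify against a truncated Neumann series on the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import floyd_warshall as _csgraph_fw

from .network_model import HomologyMap, LabeledGraph, Neighborhood

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "RandomWalkConvergenceError",
    "floyd_warshall",
    "shortest_path_kernel",
    "random_walk_kernel",
    "DEFAULT_LAMBDA",
    "SP_EPSILON_UNIT",
    "SP_EPSILON_CORRELATION",
]

DEFAULT_LAMBDA = 0.01
SP_EPSILON_UNIT = 0.0
SP_EPSILON_CORRELATION = 0.05

WEIGHT_MODES = ("unit", "correlation_distance")


class RandomWalkConvergenceError(ValueError):
    """lambda * spectral_radius(K) >= 1: the walk series diverges."""


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths; unreachable pairs hold +inf."""

    nodes: tuple[str, ...]
    d: np.ndarray  # square, zero diagonal, symmetric

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def distance(self, u: str, v: str) -> float:
        return float(self.d[self.nodes.index(u), self.nodes.index(v)])


def _edge_length(w: float, weight_mode: str) -> float:
    # High correlation => short distance; unit mode ignores weights.
    return 1.0 if weight_mode == "unit" else 1.0 - w


def _check_mode(g: LabeledGraph, weight_mode: str) -> None:
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if weight_mode == "correlation_distance" and not g.weighted:
        raise ValueError("correlation_distance mode requires a weighted graph")


def floyd_warshall(g: LabeledGraph, weight_mode: str = "unit") -> DistanceMatrix:
    """All-pairs shortest paths with edge length 1 (unit) or 1 - weight."""
    _check_mode(g, weight_mode)
    nodes = tuple(g.sorted_nodes())
    n = len(nodes)
    if n == 0:
        return DistanceMatrix(nodes=nodes, d=np.zeros((0, 0)))
    idx = {u: i for i, u in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, data in g.graph.edges(data=True):
        length = _edge_length(data.get("weight", 1.0), weight_mode)
        rows.append(idx[u])
        cols.append(idx[v])
        vals.append(length)
    adj = csr_array((vals, (rows, cols)), shape=(n, n))
    d = _csgraph_fw(adj, directed=False, unweighted=(weight_mode == "unit"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(nodes=nodes, d=d)


def _homology_weights(P) -> dict[tuple[str, str], float]:
    if isinstance(P, HomologyMap):
        return P.normalized()
    return dict(P)


def _supported_pairs(
    C: Neighborhood, Z: Neighborhood, hom: dict[tuple[str, str], float]
) -> list[tuple[str, str, float]]:
    c_nodes = set(C.nodes)
    z_nodes = set(Z.nodes)
    return sorted(
        (u, v, h)
        for (u, v), h in hom.items()
        if h > 0 and u in c_nodes and v in z_nodes
    )


def shortest_path_kernel(
    C: Neighborhood,
    Z: Neighborhood,
    P,
    weight_mode: str = "unit",
    epsilon: float | None = None,
    dist_c: DistanceMatrix | None = None,
    dist_z: DistanceMatrix | None = None,
) -> float:
    """Shortest-path kernel between two neighborhoods under homology map P.

    ``P`` may be a :class:`HomologyMap` (min–max normalized internally) or a
    pre-normalized ``{(u, u'): hom}`` dict.  Distance matrices may be passed
    in to reuse cached Floyd–Warshall results.
    """
    if epsilon is None:
        epsilon = SP_EPSILON_UNIT if weight_mode == "unit" else SP_EPSILON_CORRELATION
    hom = _homology_weights(P)
    support = _supported_pairs(C, Z, hom)
    if len(support) < 2:
        return 0.0
    dc = dist_c if dist_c is not None else floyd_warshall(C.subgraph, weight_mode)
    dz = dist_z if dist_z is not None else floyd_warshall(Z.subgraph, weight_mode)
    ic = {u: i for i, u in enumerate(dc.nodes)}
    iz = {v: i for i, v in enumerate(dz.nodes)}
    total = 0.0
    for u, up, h1 in support:
        for v, vp, h2 in support:
            if u == v or up == vp:
                continue
            d1 = dc.d[ic[u], ic[v]]
            d2 = dz.d[iz[up], iz[vp]]
            if np.isinf(d1) or np.isinf(d2):
                continue
            if abs(d1 - d2) <= epsilon:
                total += h1 * h2
    return total


def _coupling(
    wc: float, wz: float, weight_mode: str, weight_gate: float | None
) -> float:
    if weight_mode == "unit":
        return 1.0
    if weight_gate is not None:
        # Hard similarity gate: edges match only if their correlations agree.
        return 1.0 if abs(wc - wz) <= weight_gate else 0.0
    return wc * wz


def random_walk_kernel(
    C: Neighborhood,
    Z: Neighborhood,
    P,
    lam: float = DEFAULT_LAMBDA,
    weight_mode: str = "unit",
    weight_gate: float | None = None,
) -> float:
    """Random-walk kernel p (I - lambda K)^{-1} q between two neighborhoods.

    Returns n*m when no homology couples the subgraphs (K = 0, identity
    inverse).  Raises :class:`RandomWalkConvergenceError` when
    lambda * spectral_radius(K) >= 1.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    _check_mode(C.subgraph, weight_mode)
    n = C.number_of_nodes()
    m = Z.number_of_nodes()
    if n == 0 or m == 0:
        logger.warning("empty neighborhood: random-walk kernel degenerates to n*m")
        return float(n * m)
    hom = _homology_weights(P)
    support = _supported_pairs(C, Z, hom)
    s = len(support)
    if s == 0:
        logger.debug("no homologous cross pairs: random-walk kernel = n*m")
        return float(n * m)

    gc, gz = C.subgraph, Z.subgraph
    K = np.zeros((s, s))
    for i, (u, up, hi) in enumerate(support):
        for j, (v, vp, hj) in enumerate(support):
            if gc.graph.has_edge(u, v) and gz.graph.has_edge(up, vp):
                K[i, j] = (
                    hi
                    * hj
                    * _coupling(gc.weight(u, v), gz.weight(up, vp), weight_mode, weight_gate)
                )
    if np.any(K):
        rho = float(np.max(np.abs(np.linalg.eigvals(K))))
        if lam * rho >= 1.0:
            raise RandomWalkConvergenceError(
                f"lambda * spectral_radius = {lam * rho:.6g} >= 1 "
                f"(spectral radius {rho:.6g}); reduce lambda"
            )
    ones = np.ones(s)
    x = np.linalg.solve(np.eye(s) - lam * K, ones)
    return float(n * m - s + x.sum())
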