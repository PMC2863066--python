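"""Node-importance scores and the cross-graph pair normalization.

Four whole-graph centrality measures feed the pair features: BaryCenter
(sum of shortest-path distances; smaller = more central), betweenness
(fraction of shortest paths mediated), degree, and HITS (hub + authority from
power iteration; on an undirected graph both coincide with the dominant
eigenvector of the adjacency).  Because the two species' graphs differ in
size and scale, raw scores are min–max normalized within each graph before a
pair (u, v) is scored by the agreement of the normalized values,
S(u, v) = 1 - |s_hat_u - s_hat_v| in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_model import LabeledGraph
from .graph_kernels import floyd_warshall

__all__ = [
    "ScoreStats",
    "HitsConvergenceError",
    "barycenter_scores",
    "betweenness_scores",
    "degree_scores",
    "hits_scores",
    "pair_score",
]


class HitsConvergenceError(RuntimeError):
    """HITS power iteration failed to converge within max_iter iterations."""


@dataclass(frozen=True)
class ScoreStats:
    """Min and max of a node score over one graph, for pair normalization."""

    lo: float
    hi: float

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "ScoreStats":
        vals = list(scores.values())
        return cls(lo=min(vals), hi=max(vals))

    def normalize(self, s: float) -> float:
        if self.hi == self.lo:
            return 0.0
        return (s - self.lo) / (self.hi - self.lo)


def _length_graph(g: LabeledGraph, weight_mode: str) -> tuple[nx.Graph, str | None]:
    """Annotate edges with the 1 - |rho| length used for weighted paths."""
    if weight_mode == "unit":
        return g.graph, None
    if not g.weighted:
        raise ValueError("correlation_distance mode requires a weighted graph")
    h = g.graph.copy()
    for u, v, data in h.edges(data=True):
        data["length"] = 1.0 - data.get("weight", 1.0)
    return h, "length"


def barycenter_scores(g: LabeledGraph, weight_mode: str = "unit") -> dict[str, float]:
    """BaryCenter score: sum of shortest-path lengths to all reachable nodes.

    Smaller values mark more central nodes; isolated nodes score 0.
    """
    dm = floyd_warshall(g, weight_mode)
    finite = np.where(np.isinf(dm.d), 0.0, dm.d)
    sums = finite.sum(axis=1)
    return {node: float(sums[i]) for i, node in enumerate(dm.nodes)}


def betweenness_scores(g: LabeledGraph, weight_mode: str = "unit") -> dict[str, float]:
    """Betweenness: sum over unordered (s, t) pairs of the fraction of
    shortest s–t paths passing through the node."""
    h, length_attr = _length_graph(g, weight_mode)
    raw = nx.betweenness_centrality(h, normalized=False, weight=length_attr)
    return {node: float(val) for node, val in raw.items()}


def degree_scores(g: LabeledGraph) -> dict[str, float]:
    """Degree of each node (connection count, weights ignored)."""
    return {node: float(deg) for node, deg in g.graph.degree()}


def hits_scores(
    g: LabeledGraph, max_iter: int = 1000, tol: float = 1e-8
) -> dict[str, float]:
    """HITS hub + authority scores by power iteration on the adjacency matrix.

    Hub and authority vectors are L2-normalized each sweep; iteration stops
    when both change by less than ``tol`` in L2 norm.  On an undirected graph
    the two vectors coincide, so the returned score is twice the dominant
    adjacency eigenvector (entrywise).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("HITS is undefined on an empty graph")
    nodes = g.sorted_nodes()
    A = nx.to_numpy_array(g.graph, nodelist=nodes, weight=None)
    n = len(nodes)
    hub = np.full(n, 1.0 / np.sqrt(n))
    auth = hub.copy()
    for _ in range(max_iter):
        new_auth = A.T @ hub
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth /= norm
        new_hub = A @ new_auth
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub /= norm
        delta = np.linalg.norm(new_hub - hub) + np.linalg.norm(new_auth - auth)
        hub, auth = new_hub, new_auth
        if delta < tol:
            return {node: float(hub[i] + auth[i]) for i, node in enumerate(nodes)}
    raise HitsConvergenceError(f"HITS did not converge within {max_iter} iterations")


def pair_score(
    s_u: float, s_v: float, stats_g1: ScoreStats, stats_g2: ScoreStats
) -> float:
    """Agreement of two nodes' relative importance, each min–max normalized
    within its own graph: 1 - |s_hat_u - s_hat_v|, in [0, 1].

    Normalizing per graph removes the magnitude bias between graphs of very
    different sizes.  A degenerate graph (all scores equal) normalizes to 0.
    """
    return 1.0 - abs(stats_g1.normalize(s_u) - stats_g2.normalize(s_v))
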