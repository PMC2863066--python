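"""Graph and homology containers, edge-list I/O, and k-hop neighborhood extraction.

A species network is an undirected :class:`LabeledGraph` — unweighted for
protein–protein interaction data, weighted by |Spearman rho| for gene
coexpression data.  Cross-species sequence similarity lives in a sparse
:class:`HomologyMap` (the mapping matrix P): it associates each vertex of one
graph with zero or more vertices of the other, weighted by averaged
bidirectional BLAST bit scores.  Candidate ortholog pairs are compared through
the k-hop neighborhoods extracted here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledGraph",
    "HomologyMap",
    "Neighborhood",
    "EdgeListParseError",
    "GraphValidationError",
    "MissingNodeError",
    "load_graph",
    "khop_neighborhood",
    "candidate_matches",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file (carries the 1-based line number)."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class GraphValidationError(ValueError):
    """Graph content violates an invariant (e.g. edge weight outside (0, 1])."""


class MissingNodeError(KeyError):
    """A seed vertex is absent from the graph."""


@dataclass
class LabeledGraph:
    """Undirected graph with string node IDs and optional (0, 1] edge weights.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`.  Edge weights, when present,
        are stored under the ``"weight"`` attribute.
    species
        Free-form species tag (e.g. ``"mouse"``); purely informational.
    weighted
        Whether edges carry correlation weights.  Unweighted edges are treated
        as weight 1 wherever a weight is requested.
    """

    graph: nx.Graph
    species: str = ""
    weighted: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        """Weight of edge (u, v); 1.0 on unweighted graphs."""
        return float(self.graph[u][v].get("weight", 1.0))

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def validate(self) -> None:
        for u in self.graph.nodes:
            if self.graph.has_edge(u, u):
                raise GraphValidationError(f"self-loop at node {u!r}")
        if self.weighted:
            for u, v, data in self.graph.edges(data=True):
                w = data.get("weight")
                if w is None or not (0.0 < w <= 1.0):
                    raise GraphValidationError(
                        f"edge ({u!r}, {v!r}) weight {w!r} outside (0, 1]"
                    )


@dataclass
class HomologyMap:
    """Sparse cross-graph homology map (the mapping matrix P).

    ``scores`` holds one averaged bidirectional bit score per (node-in-G1,
    node-in-G2) pair; only pairs passing the e-value cutoff appear.  The raw
    direction-resolved scores are retained (``forward`` is G1-query→G2-subject,
    ``reverse`` is G2-query→G1-subject, both keyed as (g1_node, g2_node)) so
    the reciprocal-best-hit baseline can be computed from the same object.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    forward: dict[tuple[str, str], float] = field(default_factory=dict)
    reverse: dict[tuple[str, str], float] = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self.scores.items()))

    def score(self, u: str, v: str) -> float:
        return self.scores[(u, v)]

    def matches_of(self, vertex: str) -> list[str]:
        """All G2 nodes paired with ``vertex``, sorted by ID."""
        return sorted(v for (u, v) in self.scores if u == vertex)

    def swapped(self) -> "HomologyMap":
        """The same map with the species roles exchanged."""
        flip = lambda d: {(b, a): s for (a, b), s in d.items()}
        return HomologyMap(
            scores=flip(self.scores), forward=flip(self.reverse), reverse=flip(self.forward)
        )

    def normalized(self) -> dict[tuple[str, str], float]:
        """Min–max normalize averaged scores to [0, 1] over all pairs.

        Keeps kernel magnitudes independent of the bit-score scale.  When all
        scores are equal the normalization is degenerate and every pair gets
        weight 1.
        """
        if not self.scores:
            return {}
        vals = self.scores.values()
        lo, hi = min(vals), max(vals)
        if math.isclose(lo, hi):
            return {pair: 1.0 for pair in self.scores}
        span = hi - lo
        return {pair: (s - lo) / span for pair, s in self.scores.items()}


@dataclass
class Neighborhood:
    """The k-hop subgraph induced around a seed vertex.

    Hops are counted topologically (edge weights are ignored for reachability);
    all edges among retained nodes are kept, including edges joining two
    outermost-hop nodes.
    """

    seed: str
    k: int
    subgraph: LabeledGraph

    @property
    def nodes(self) -> set[str]:
        return self.subgraph.nodes

    def number_of_nodes(self) -> int:
        return self.subgraph.number_of_nodes()


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def load_graph(
    source,
    weighted: bool = False,
    species_tag: str = "",
    header: bool = False,
) -> LabeledGraph:
    """Read an undirected graph from a tab-separated edge list.

    Format: ``node_a<TAB>node_b[<TAB>weight]`` (any whitespace accepted),
    comment lines start with ``#``.  Duplicate edges are collapsed keeping the
    maximum weight; self-loops are dropped with a logged warning (the node is
    retained).  Weights must lie in (0, 1].

    Parameters
    ----------
    source
        Path or iterable of lines.
    weighted
        Whether a third weight column is required.
    species_tag
        Species label attached to the returned graph.
    header
        Skip the first non-comment line.
    """
    g = nx.Graph()
    skipped_header = not header
    dropped_loops = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not skipped_header:
            skipped_header = True
            continue
        parts = line.split()
        expected = 3 if weighted else 2
        if len(parts) < expected:
            raise EdgeListParseError(
                lineno, f"expected {expected} columns, found {len(parts)}"
            )
        u, v = parts[0], parts[1]
        if u == v:
            dropped_loops += 1
            g.add_node(u)
            continue
        if weighted:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise EdgeListParseError(lineno, f"bad weight {parts[2]!r}") from exc
            if not (0.0 < w <= 1.0):
                raise GraphValidationError(
                    f"line {lineno}: weight {w} outside (0, 1]"
                )
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        else:
            g.add_edge(u, v)
    if dropped_loops:
        logger.warning("dropped %d self-loop(s) while loading edge list", dropped_loops)
    return LabeledGraph(graph=g, species=species_tag, weighted=weighted)


def khop_neighborhood(g: LabeledGraph, seed: str, k: int) -> Neighborhood:
    """Extract the k-hop neighborhood C_x of ``seed``.

    Breadth-first hop counting ignores edge weights; the subgraph is the one
    induced by all vertices within ``k`` hops (frontier–frontier edges kept).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if seed not in g.graph:
        raise MissingNodeError(seed)
    reachable = nx.single_source_shortest_path_length(g.graph, seed, cutoff=k)
    sub = g.graph.subgraph(reachable).copy()
    return Neighborhood(
        seed=seed,
        k=k,
        subgraph=LabeledGraph(graph=sub, species=g.species, weighted=g.weighted),
    )


def candidate_matches(P: HomologyMap, vertex: str) -> list[str]:
    """G2 vertices homologous to ``vertex`` under P, sorted by ID (may be empty)."""
    return P.matches_of(vertex)
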