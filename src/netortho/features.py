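"""Assembly of the 9-feature vector for each BLAST-matched candidate pair.

For a candidate pair (u, v) the features are: the averaged BLAST bit score;
the random-walk and shortest-path kernels over the 1-hop and 2-hop
neighborhoods of u and v; and the normalized pair agreements of four
whole-graph centralities (BaryCenter, betweenness, degree, HITS).  The
candidate universe is exactly the pairs in the homology map P — pairs without
sequence homology are never scored — and labels mark which candidates belong
to a curated orthology group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import (
    ScoreStats,
    barycenter_scores,
    betweenness_scores,
    degree_scores,
    hits_scores,
    pair_score,
)
from .config import PipelineConfig
from .graph_kernels import (
    DistanceMatrix,
    floyd_warshall,
    random_walk_kernel,
    shortest_path_kernel,
)
from .network_model import HomologyMap, LabeledGraph, Neighborhood, khop_neighborhood

logger = logging.getLogger(__name__)

__all__ = ["PairFeatureVector", "FeatureComputer", "feature_vector", "feature_table",
           "FEATURE_COLUMNS", "TABLE_COLUMNS"]

FEATURE_COLUMNS = [
    "blast", "rw1", "sp1", "rw2", "sp2", "barycenter", "betweenness", "degree", "hits",
]
TABLE_COLUMNS = ["node_a", "node_b"] + FEATURE_COLUMNS + ["label"]

LABEL_POSITIVE = "ortholog"
LABEL_NEGATIVE = "non-ortholog"


@dataclass(frozen=True)
class PairFeatureVector:
    """The 9 scores for one candidate pair, plus its orthology label."""

    pair: tuple[str, str]
    blast: float
    rw1: float
    sp1: float
    rw2: float
    sp2: float
    barycenter: float
    betweenness: float
    degree: float
    hits: float
    label: str = "unknown"

    def as_array(self) -> np.ndarray:
        vec = np.array(
            [self.blast, self.rw1, self.sp1, self.rw2, self.sp2,
             self.barycenter, self.betweenness, self.degree, self.hits]
        )
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite feature for pair {self.pair}: {vec}")
        return vec

    def as_row(self) -> dict:
        row = {"node_a": self.pair[0], "node_b": self.pair[1]}
        row.update(zip(FEATURE_COLUMNS, self.as_array()))
        row["label"] = self.label
        return row


class FeatureComputer:
    """Caches per-graph centralities, neighborhoods, and distance matrices so
    a full feature table costs one centrality pass per graph."""

    _CENTRALITIES = ("barycenter", "betweenness", "degree", "hits")

    def __init__(
        self,
        g1: LabeledGraph,
        g2: LabeledGraph,
        P: HomologyMap,
        config: PipelineConfig | None = None,
    ):
        self.g1, self.g2, self.P = g1, g2, P
        self.config = config or PipelineConfig()
        self.hom = P.normalized()
        self._mode = {
            id(g1): "correlation_distance" if g1.weighted else "unit",
            id(g2): "correlation_distance" if g2.weighted else "unit",
        }
        self._scores: dict[tuple[int, str], dict[str, float]] = {}
        self._stats: dict[tuple[int, str], ScoreStats] = {}
        for g in (g1, g2):
            if g.number_of_nodes() == 0:
                continue
            mode = self._mode[id(g)]
            computed = {
                "barycenter": barycenter_scores(g, mode),
                "betweenness": betweenness_scores(g, mode),
                "degree": degree_scores(g),
                "hits": hits_scores(
                    g, self.config.hits_max_iter, self.config.hits_tol
                ),
            }
            for name, scores in computed.items():
                self._scores[(id(g), name)] = scores
                self._stats[(id(g), name)] = ScoreStats.from_scores(scores)
        self._hoods: dict[tuple[int, str, int], Neighborhood] = {}
        self._dists: dict[tuple[int, str, int], DistanceMatrix] = {}

    def _neighborhood(self, g: LabeledGraph, node: str, k: int) -> Neighborhood:
        key = (id(g), node, k)
        if key not in self._hoods:
            self._hoods[key] = khop_neighborhood(g, node, k)
        return self._hoods[key]

    def _distances(self, g: LabeledGraph, node: str, k: int) -> DistanceMatrix:
        key = (id(g), node, k)
        if key not in self._dists:
            hood = self._neighborhood(g, node, k)
            self._dists[key] = floyd_warshall(hood.subgraph, self._mode[id(g)])
        return self._dists[key]

    def _kernels(self, u: str, v: str, k: int) -> tuple[float, float]:
        cfg = self.config
        C = self._neighborhood(self.g1, u, k)
        Z = self._neighborhood(self.g2, v, k)
        mode_c = self._mode[id(self.g1)]
        mode_z = self._mode[id(self.g2)]
        # Kernels need one mode for both sides; mixed PPI/coexpression
        # comparisons fall back to topology-only (unit) distances.
        mode = mode_c if mode_c == mode_z else "unit"
        eps = cfg.sp_epsilon_unit if mode == "unit" else cfg.sp_epsilon_correlation
        sp = shortest_path_kernel(
            C, Z, self.hom, weight_mode=mode, epsilon=eps,
            dist_c=self._distances(self.g1, u, k) if mode == mode_c else None,
            dist_z=self._distances(self.g2, v, k) if mode == mode_z else None,
        )
        rw = random_walk_kernel(
            C, Z, self.hom, lam=cfg.lam, weight_mode=mode,
            weight_gate=cfg.rw_weight_gate,
        )
        return rw, sp

    def feature_vector(self, u: str, v: str, label: str = "unknown") -> PairFeatureVector:
        if (u, v) not in self.P:
            raise ValueError(f"pair ({u!r}, {v!r}) is not in the homology map")
        rw1, sp1 = self._kernels(u, v, 1)
        rw2, sp2 = self._kernels(u, v, 2)
        cent = {}
        for name in self._CENTRALITIES:
            cent[name] = pair_score(
                self._scores[(id(self.g1), name)][u],
                self._scores[(id(self.g2), name)][v],
                self._stats[(id(self.g1), name)],
                self._stats[(id(self.g2), name)],
            )
        return PairFeatureVector(
            pair=(u, v),
            blast=self.P.score(u, v),
            rw1=rw1, sp1=sp1, rw2=rw2, sp2=sp2,
            barycenter=cent["barycenter"],
            betweenness=cent["betweenness"],
            degree=cent["degree"],
            hits=cent["hits"],
            label=label,
        )

    def feature_table(self, labels: set[tuple[str, str]] | None = None) -> pd.DataFrame:
        """One row per homology-map pair, in sorted pair order.

        ``labels`` is the curated ortholog pair set; pairs in it are labeled
        positive, all other candidates negative.
        """
        labels = labels or set()
        if len(self.P) == 0:
            logger.warning("homology map is empty: emitting an empty feature table")
        rows = []
        for (u, v), _ in self.P.items():
            lab = LABEL_POSITIVE if (u, v) in labels else LABEL_NEGATIVE
            rows.append(self.feature_vector(u, v, label=lab).as_row())
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def feature_vector(
    u: str,
    v: str,
    g1: LabeledGraph,
    g2: LabeledGraph,
    P: HomologyMap,
    config: PipelineConfig | None = None,
) -> PairFeatureVector:
    """Convenience wrapper computing a single pair's features from scratch."""
    return FeatureComputer(g1, g2, P, config).feature_vector(u, v)


def feature_table(
    g1: LabeledGraph,
    g2: LabeledGraph,
    P: HomologyMap,
    labels: set[tuple[str, str]] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Labeled feature table over every candidate pair in P (sorted, reproducible)."""
    return FeatureComputer(g1, g2, P, config).feature_table(labels)
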