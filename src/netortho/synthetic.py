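"""Synthetic paired networks, homology scores, labels, and expression data.

The generator plants a known orthology between two species so every pipeline
stage is testable without downloads.  Species 1 is an Erdős–Rényi graph (a
preferential-attachment option approximates the heavy-tailed degree
distributions of real interactomes); species 2 is a node-renamed copy whose
edges are independently rewired with a set probability, emulating
interactome divergence.  True ortholog pairs receive bit-score-like homology
values around 500, decoy (spurious) pairs around 150, each split into two
slightly asymmetric BLAST directions whose average recovers the pair score.
Expression matrices group genes into co-regulated modules sharing latent
tissue profiles, with orthologous genes sharing the same profile across
species, so coexpression networks thresholded at |rho| >= 0.8 recover module
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .homology import average_bidirectional
from .network_model import HomologyMap, LabeledGraph

__all__ = [
    "SyntheticPair",
    "generate_network_pair",
    "generate_expression_pair",
    "write_edge_list",
    "write_blast_tabular",
    "write_labels",
    "NETWORK_DEFAULTS",
    "EXPRESSION_DEFAULTS",
]

# Default study conditions for the synthetic benchmark.
NETWORK_DEFAULTS = dict(
    n=100, edge_prob=0.08, rewire_rate=0.1, ortholog_fraction=0.5, decoy_rate=0.1
)
EXPRESSION_DEFAULTS = dict(n_genes=50, n_tissues=13, module_count=5, noise_sd=0.25)

ORTHOLOG_SCORE_MEAN, ORTHOLOG_SCORE_SD = 500.0, 50.0
DECOY_SCORE_MEAN, DECOY_SCORE_SD = 150.0, 50.0
DIRECTION_JITTER_SD = 10.0
SYNTHETIC_EVALUE = 1e-50


@dataclass
class SyntheticPair:
    """A generated two-species instance with planted orthology."""

    g1: LabeledGraph
    g2: LabeledGraph
    P: HomologyMap
    labels: set[tuple[str, str]]
    ab_table: dict[tuple[str, str], float]
    ba_table: dict[tuple[str, str], float]


def _node_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _base_graph(n: int, edge_prob: float, model: str, rng: np.random.Generator) -> nx.Graph:
    seed = int(rng.integers(0, 2**31 - 1))
    if model == "erdos_renyi":
        return nx.gnp_random_graph(n, edge_prob, seed=seed)
    if model == "preferential_attachment":
        m = max(1, round(edge_prob * (n - 1) / 2))
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ValueError(f"unknown network model {model!r}")


def _rewired_copy(g: nx.Graph, rewire_rate: float, rng: np.random.Generator) -> nx.Graph:
    """Copy of g with each edge independently rewired with probability rewire_rate."""
    h = g.copy()
    nodes = sorted(h.nodes)
    for u, v in sorted(g.edges):
        if rng.random() >= rewire_rate:
            continue
        h.remove_edge(u, v)
        keep, _drop = (u, v) if rng.random() < 0.5 else (v, u)
        for _attempt in range(20):
            w = nodes[rng.integers(len(nodes))]
            if w != keep and not h.has_edge(keep, w):
                h.add_edge(keep, w)
                break
        else:  # dense corner: give the edge back rather than lose it
            h.add_edge(u, v)
    return h


def _truncated_normal(
    mean: float, sd: float, rng: np.random.Generator, lo: float = 1.0
) -> float:
    return max(lo, float(rng.normal(mean, sd)))


def generate_network_pair(
    n: int = NETWORK_DEFAULTS["n"],
    edge_prob: float = NETWORK_DEFAULTS["edge_prob"],
    rewire_rate: float = NETWORK_DEFAULTS["rewire_rate"],
    ortholog_fraction: float = NETWORK_DEFAULTS["ortholog_fraction"],
    decoy_rate: float = NETWORK_DEFAULTS["decoy_rate"],
    seed: int = 0,
    model: str = "erdos_renyi",
) -> SyntheticPair:
    """Generate two networks with planted orthologs and decoy homology.

    Species 2 is a renamed copy of species 1 with edges rewired at
    ``rewire_rate``.  A fraction ``ortholog_fraction`` of nodes are true
    orthologs (positive labels) with homology scores ~ Normal(500, 50)
    truncated at 1; round(``decoy_rate`` * n) decoy entries link
    non-corresponding nodes with scores ~ Normal(150, 50) truncated at 1.
    Deterministic given ``seed``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    for name, rate in [
        ("edge_prob", edge_prob),
        ("rewire_rate", rewire_rate),
        ("ortholog_fraction", ortholog_fraction),
        ("decoy_rate", decoy_rate),
    ]:
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    names1 = _node_names("a", n)
    names2 = _node_names("b", n)

    base = _base_graph(n, edge_prob, model, rng)
    g1 = nx.relabel_nodes(base, dict(enumerate(names1)))
    g2 = nx.relabel_nodes(_rewired_copy(base, rewire_rate, rng), dict(enumerate(names2)))

    n_orth = round(ortholog_fraction * n)
    orth_idx = sorted(rng.choice(n, size=n_orth, replace=False))
    labels = {(names1[i], names2[i]) for i in orth_idx}

    ab: dict[tuple[str, str], float] = {}
    ba: dict[tuple[str, str], float] = {}

    def add_entry(a: str, b: str, mean: float, sd: float) -> None:
        jitter = rng.normal(0.0, DIRECTION_JITTER_SD)
        mu = _truncated_normal(mean, sd, rng)
        ab[(a, b)] = max(1.0, mu + jitter)
        ba[(b, a)] = max(1.0, mu - jitter)

    for i in orth_idx:
        add_entry(names1[i], names2[i], ORTHOLOG_SCORE_MEAN, ORTHOLOG_SCORE_SD)

    n_decoys = round(decoy_rate * n)
    decoy_sources = sorted(rng.choice(n, size=min(n_decoys, n), replace=False))
    for i in decoy_sources:
        for _attempt in range(20):
            j = int(rng.integers(n))
            if j != i and (names1[i], names2[j]) not in ab:
                add_entry(names1[i], names2[j], DECOY_SCORE_MEAN, DECOY_SCORE_SD)
                break

    P = average_bidirectional(ab, ba)
    return SyntheticPair(
        g1=LabeledGraph(graph=g1, species="species1"),
        g2=LabeledGraph(graph=g2, species="species2"),
        P=P,
        labels=labels,
        ab_table=ab,
        ba_table=ba,
    )


def generate_expression_pair(
    n_genes: int = EXPRESSION_DEFAULTS["n_genes"],
    n_tissues: int = EXPRESSION_DEFAULTS["n_tissues"],
    module_count: int = EXPRESSION_DEFAULTS["module_count"],
    noise_sd: float = EXPRESSION_DEFAULTS["noise_sd"],
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two species' genes × tissues matrices with shared co-regulated modules.

    Gene i belongs to module i mod ``module_count``; every gene's profile is
    its module's latent tissue profile plus Normal(0, noise_sd) noise, and
    orthologous genes (same index across species) share the same latent
    profile.  Deterministic given ``seed``.
    """
    if n_tissues < 5:
        raise ValueError("n_tissues must be >= 5")
    if module_count < 1 or module_count > n_genes:
        raise ValueError("module_count must lie in [1, n_genes]")
    rng = np.random.default_rng(seed)
    tissues = [f"tissue{t:02d}" for t in range(n_tissues)]
    latent = rng.normal(size=(module_count, n_tissues))
    out = []
    for prefix in ("a", "b"):
        genes = _node_names(prefix, n_genes)
        values = np.vstack(
            [
                latent[i % module_count] + rng.normal(0.0, noise_sd, size=n_tissues)
                if noise_sd > 0
                else latent[i % module_count]
                for i in range(n_genes)
            ]
        )
        out.append(ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues)))
    return out[0], out[1]


def write_edge_list(g: LabeledGraph, path) -> None:
    """Emit the edge-list TSV consumed by :func:`netortho.network_model.load_graph`.

    Isolated nodes are written as self-pair lines (``u<TAB>u``): the loader
    drops the self-loop but retains the node, so the round trip preserves the
    node set.
    """
    with open(path, "wt", encoding="utf-8") as handle:
        for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges):
            if g.weighted:
                handle.write(f"{u}\t{v}\t{g.weight(u, v):.6f}\n")
            else:
                handle.write(f"{u}\t{v}\n")
        for u in sorted(nx.isolates(g.graph)):
            if g.weighted:
                handle.write(f"{u}\t{u}\t1.0\n")
            else:
                handle.write(f"{u}\t{u}\n")


def write_blast_tabular(table: dict[tuple[str, str], float], path) -> None:
    """Emit a directional score table as 12-column BLAST outfmt-6 text."""
    with open(path, "wt", encoding="utf-8") as handle:
        for (q, s), score in sorted(table.items()):
            handle.write(
                f"{q}\t{s}\t95.00\t100\t5\t0\t1\t100\t1\t100\t"
                f"{SYNTHETIC_EVALUE:.0e}\t{score:.1f}\n"
            )


def write_labels(labels: set[tuple[str, str]], path) -> None:
    """Emit ortholog labels as a two-column pair TSV."""
    with open(path, "wt", encoding="utf-8") as handle:
        for a, b in sorted(labels):
            handle.write(f"{a}\t{b}\n")
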