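"""Weighted gene-coexpression network construction.

Expression is summarized to one value per gene per tissue (probe rows mapped
to genes and averaged), all pairwise Spearman rank correlations are computed,
and gene pairs with |rho| at or above a cutoff (default 0.8) become edges
weighted by |rho|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network_model import LabeledGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "average_probes",
    "spearman_rho",
    "build_coexpression_network",
    "DEFAULT_CORRELATION_CUTOFF",
]

DEFAULT_CORRELATION_CUTOFF = 0.8


@dataclass
class ExpressionMatrix:
    """Genes × tissues expression values (one averaged value per gene per tissue)."""

    values: pd.DataFrame  # index: gene IDs, columns: tissue labels

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV with gene IDs in the first column and a tissue header row."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def average_probes(probe_matrix: pd.DataFrame, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse a probe × tissue matrix to gene level by averaging probe rows.

    Probes without a gene mapping are dropped (count logged).  Raises if no
    probe maps to any gene.
    """
    mapped = probe_matrix.index.to_series().map(probe_to_gene)
    dropped = int(mapped.isna().sum())
    if dropped:
        logger.info("dropped %d probe(s) without a gene mapping", dropped)
    kept = probe_matrix.loc[mapped.notna()]
    if kept.empty:
        raise ValueError("no probes map to any gene: empty output")
    genes = mapped.dropna()
    collapsed = kept.groupby(genes).mean().sort_index()
    return ExpressionMatrix(collapsed)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average-rank vectors.

    Returns NaN when either vector is constant (undefined correlation).
    Vectors must have equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a rank correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def build_coexpression_network(
    em: ExpressionMatrix,
    cutoff: float = DEFAULT_CORRELATION_CUTOFF,
    species_tag: str = "",
) -> LabeledGraph:
    """Threshold pairwise |Spearman rho| into a weighted coexpression graph.

    Edge (g1, g2) with weight |rho| is created iff |rho| >= cutoff.  Genes with
    constant expression have undefined correlations and are excluded from
    pairing but retained as isolated nodes, as are genes below the cutoff with
    every partner.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    mat = em.values
    if len(mat) < 2:
        raise ValueError("need at least 2 genes to build a coexpression network")
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 conditions for rank correlations")

    genes = list(mat.index)
    ranks = np.apply_along_axis(stats.rankdata, 1, mat.to_numpy(dtype=float))
    variable = np.ptp(ranks, axis=1) > 0

    g = nx.Graph()
    g.add_nodes_from(genes)
    idx = np.flatnonzero(variable)
    if idx.size >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(ranks[idx])
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                rho = corr[a, b]
                if np.isfinite(rho) and abs(rho) >= cutoff:
                    g.add_edge(
                        genes[idx[a]],
                        genes[idx[b]],
                        weight=min(abs(float(rho)), 1.0),
                    )
    return LabeledGraph(graph=g, species=species_tag, weighted=True)
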