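"""BLAST tabular ingestion, bidirectional score averaging, and the RBH baseline.

Sequence similarity is consumed, never computed: both BLAST directions are
parsed from 12-column tabular output (outfmt 6), filtered at an e-value
cutoff (default 1e-10), and their bit scores averaged into the
:class:`~netortho.network_model.HomologyMap` that drives every downstream
feature.  The reciprocal-best-hit baseline predicts (a, b) orthologous iff b
is a's top-scoring match and a is b's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .network_model import HomologyMap

logger = logging.getLogger(__name__)

__all__ = [
    "BlastParseError",
    "RbhPrediction",
    "parse_blast_tabular",
    "average_bidirectional",
    "rbh_predict",
    "DEFAULT_EVALUE_CUTOFF",
]

DEFAULT_EVALUE_CUTOFF = 1e-10
_BLAST_COLUMNS = 12


class BlastParseError(ValueError):
    """Malformed BLAST tabular line (carries the 1-based line number)."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class RbhPrediction:
    """One reciprocal-best-hit ortholog call; ``tie`` marks a broken score tie."""

    a: str
    b: str
    score: float
    tie: bool = False


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def parse_blast_tabular(
    source, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[tuple[str, str], float]:
    """Parse one direction of BLAST outfmt-6 output into (query, subject) → bit score.

    Rows with e-value above the cutoff are dropped; duplicate (query, subject)
    rows (multiple HSPs) keep the maximum bit score.
    """
    table: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != _BLAST_COLUMNS:
            raise BlastParseError(
                lineno, f"expected {_BLAST_COLUMNS} columns, found {len(parts)}"
            )
        query, subject = parts[0], parts[1]
        try:
            evalue = float(parts[10])
            bitscore = float(parts[11])
        except ValueError as exc:
            raise BlastParseError(lineno, f"bad numeric field: {exc}") from exc
        if evalue > evalue_cutoff:
            continue
        key = (query, subject)
        if key not in table or bitscore > table[key]:
            table[key] = bitscore
    return table


def average_bidirectional(
    ab: dict[tuple[str, str], float], ba: dict[tuple[str, str], float]
) -> HomologyMap:
    """Average the two directions' bit scores into a HomologyMap.

    ``ab`` is keyed (g1_node, g2_node), ``ba`` (g2_node, g1_node).  Pairs hit
    in only one direction keep that single score (count logged).
    """
    reverse = {(a, b): s for (b, a), s in ba.items()}
    pairs = set(ab) | set(reverse)
    scores: dict[tuple[str, str], float] = {}
    one_sided = 0
    for pair in pairs:
        hits = [t[pair] for t in (ab, reverse) if pair in t]
        if len(hits) == 1:
            one_sided += 1
        scores[pair] = sum(hits) / len(hits)
    if one_sided:
        logger.info("%d pair(s) hit in only one BLAST direction", one_sided)
    return HomologyMap(scores=scores, forward=dict(ab), reverse=reverse)


def _best_matches(
    grouped: dict[str, list[tuple[str, float]]]
) -> dict[str, tuple[str, bool]]:
    """Per source node: highest-scoring partner, lexicographic tie-break, tie flag."""
    best: dict[str, tuple[str, bool]] = {}
    for node, partners in grouped.items():
        top = max(s for _, s in partners)
        tied = sorted(p for p, s in partners if s == top)
        best[node] = (tied[0], len(tied) > 1)
    return best


def rbh_predict(P: HomologyMap) -> list[RbhPrediction]:
    """Reciprocal-best-hit ortholog predictions from averaged scores.

    (a, b) is predicted iff b maximizes score(a, ·) and a maximizes
    score(·, b).  Score ties are broken toward the lexicographically smallest
    partner and flagged.  The result is a partial matching: every node appears
    in at most one prediction.
    """
    by_a: dict[str, list[tuple[str, float]]] = {}
    by_b: dict[str, list[tuple[str, float]]] = {}
    for (a, b), s in P.scores.items():
        by_a.setdefault(a, []).append((b, s))
        by_b.setdefault(b, []).append((a, s))
    best_a = _best_matches(by_a)
    best_b = _best_matches(by_b)
    out = []
    for a in sorted(best_a):
        b, tie_a = best_a[a]
        back, tie_b = best_b[b]
        if back == a:
            out.append(RbhPrediction(a=a, b=b, score=P.scores[(a, b)], tie=tie_a or tie_b))
    return out
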