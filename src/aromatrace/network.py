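"""Thresholded Pearson correlation networks across stages.

Nodes are (stage, compound) pairs; an edge is kept when the Pearson
correlation over shared samples satisfies |r| > ``r_min`` and the
two-sided p-value (t-test with n − 2 degrees of freedom) satisfies
p < ``p_max`` — both strict, matching the published filter
(|r| > 0.8, p < 0.01).  No multiple-testing correction is applied by
default; a Benjamini–Hochberg option is available.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConstantVectorError, ValidationError
from .types import AbundanceMatrix, check_aligned

__all__ = ["CorrelationEdge", "pearson_r_p", "build_network", "write_edges", "to_graphml"]

logger = logging.getLogger(__name__)

Node = tuple[str, str]  # (stage name, canonical compound name)


@dataclass(frozen=True)
class CorrelationEdge:
    """A thresholded association between two (stage, compound) nodes."""

    node_a: Node
    node_b: Node
    r: float
    p: float
    n: int

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValidationError("field 'node_b' must differ from node_a")
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"field 'r' must lie in [-1, 1], got {self.r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"field 'p' must lie in [0, 1], got {self.p}")
        if self.n < 3:
            raise ValidationError(f"field 'n' must be >= 3, got {self.n}")


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    Constant vectors have no defined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"field 'y': length {y.size} does not match x length {x.size}")
    if x.size < 3:
        raise ValidationError(f"need n >= 3 samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(
    matrices: Sequence[AbundanceMatrix],
    r_min: float = 0.8,
    p_max: float = 0.01,
    pairing: str = "INTER_STAGE",
    bh_correct: bool = False,
) -> list[CorrelationEdge]:
    """All node pairs passing the strict |r| > r_min, p < p_max filter.

    ``pairing="INTER_STAGE"`` keeps only pairs whose nodes come from
    different stages; ``"ALL_PAIRS"`` tests every unordered pair.  ND
    abundances enter as 0; constant columns are skipped with a logged
    warning.  Edges are returned in lexicographic node order.
    """
    if pairing not in ("INTER_STAGE", "ALL_PAIRS"):
        raise ValidationError(f"field 'pairing' must be INTER_STAGE or ALL_PAIRS, got {pairing!r}")
    check_aligned(list(matrices))
    columns: dict[Node, np.ndarray] = {}
    for m in matrices:
        filled = m.filled()
        for name in m.compound_names:
            vec = filled[name].to_numpy(dtype=float)
            node = (m.stage.value, name)
            if np.ptp(vec) == 0:
                logger.warning("skipping constant column %s/%s", *node)
                continue
            columns[node] = vec
    nodes = sorted(columns)
    tested: list[tuple[Node, Node, float, float, int]] = []
    for a, b in combinations(nodes, 2):
        if pairing == "INTER_STAGE" and a[0] == b[0]:
            continue
        r, p = pearson_r_p(columns[a], columns[b])
        tested.append((a, b, r, p, columns[a].size))
    if bh_correct and tested:
        adj = multipletests([t[3] for t in tested], method="fdr_bh")[1]
        tested = [(a, b, r, float(q), n) for (a, b, r, _, n), q in zip(tested, adj)]
    return [
        CorrelationEdge(node_a=a, node_b=b, r=r, p=p, n=n)
        for a, b, r, p, n in tested
        if abs(r) > r_min and p < p_max
    ]


def write_edges(edges: Sequence[CorrelationEdge], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage_a", "compound_a", "stage_b", "compound_b", "r", "p", "n"])
        for e in edges:
            writer.writerow([*e.node_a, *e.node_b, repr(e.r), repr(e.p), e.n])
    return path


def to_graphml(edges: Sequence[CorrelationEdge], path: str | Path) -> Path:
    """Export the edge list for external network-visualization tools."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node("|".join(e.node_a), stage=e.node_a[0], compound=e.node_a[1])
        g.add_node("|".join(e.node_b), stage=e.node_b[0], compound=e.node_b[1])
        g.add_edge("|".join(e.node_a), "|".join(e.node_b), r=e.r, p=e.p, n=e.n)
    nx.write_graphml(g, str(path))
    return Path(path)
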