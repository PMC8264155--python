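"""Linearization quality metrics: WRJ, WFA, average cut width, edge classes.

* WRJ (weighted reversing join): total weight of edges joining two in-sides
  or two out-sides — strand inconsistency along represented genomes.
* WFA (weighted feedback arc): total weight of out->in edges pointing
  backward in the order.
* ACW (average cut width): mean number of edges crossing the |V|-1 cuts
  placed between consecutive node positions; a proxy for how far apart the
  layout places adjacent sequence.

Classification here is a pure function of (orient, order), independent of
how the linearization was produced; it doubles as a cross-check of the
classes the incremental algorithm records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EdgeClass, Linearization, is_out_side
from .graph import BidirectedGraph, Edge


@dataclass
class MetricReport:
    wrj: float
    wfa: float
    acw: float
    counts: dict[EdgeClass, int]

    def to_tsv(self) -> str:
        return "wrj\twfa\tacw\n" f"{self.wrj:g}\t{self.wfa:g}\t{self.acw:g}"


def classify_edge(edge: Edge, lin: Linearization) -> EdgeClass:
    (a, sa), (b, sb) = edge.endpoints()
    out_a = is_out_side(sa, lin.orient[a])
    out_b = is_out_side(sb, lin.orient[b])
    if out_a == out_b:
        return EdgeClass.REVERSING_JOIN
    u, v = (a, b) if out_a else (b, a)  # out-side endpoint first
    if lin.order[u] < lin.order[v]:
        return EdgeClass.FORWARD_ARC
    return EdgeClass.FEEDBACK_ARC


def classify_edges(graph: BidirectedGraph, lin: Linearization) -> dict[Edge, EdgeClass]:
    for v in graph.sequences:
        if v not in lin.orient or v not in lin.order:
            raise ValueError(f"linearization misses node {v!r}")
    return {edge: classify_edge(edge, lin) for edge in graph.edges}


def _class_weight(graph: BidirectedGraph, lin: Linearization, cls: EdgeClass) -> float:
    return sum(
        w for edge, w in graph.edges.items() if classify_edge(edge, lin) is cls
    )


def wrj(graph: BidirectedGraph, lin: Linearization) -> float:
    """Total weight of reversing joins."""
    return _class_weight(graph, lin, EdgeClass.REVERSING_JOIN)


def wfa(graph: BidirectedGraph, lin: Linearization) -> float:
    """Total weight of feedback arcs."""
    return _class_weight(graph, lin, EdgeClass.FEEDBACK_ARC)


def acw(graph: BidirectedGraph, lin: Linearization, weighted: bool = False) -> float:
    """Average cut width over the |V|-1 cuts between consecutive positions.

    An edge with endpoint positions p < q crosses the cuts p..q-1.  By
    default each edge counts once regardless of weight; ``weighted`` sums
    weights instead.  Self edges never cross a cut.  Single-node graphs
    have no cuts and score 0.  One +1/-1 difference sweep, O(|E| + |V|).
    """
    n = len(graph)
    if n <= 1:
        return 0.0
    diff = np.zeros(n + 1)
    for edge, w in graph.edges.items():
        p, q = lin.order[edge.a], lin.order[edge.b]
        if p == q:
            continue
        lo, hi = (p, q) if p < q else (q, p)
        contribution = w if weighted else 1.0
        diff[lo] += contribution
        diff[hi] -= contribution
    widths = np.cumsum(diff[1:n])  # width of cut i, for i = 1..n-1
    return float(widths.mean())


def report(
    graph: BidirectedGraph, lin: Linearization, weighted_acw: bool = False
) -> MetricReport:
    classes = classify_edges(graph, lin)
    counts = {cls: 0 for cls in EdgeClass}
    totals = {cls: 0.0 for cls in EdgeClass}
    for edge, cls in classes.items():
        counts[cls] += 1
        totals[cls] += graph.edges[edge]
    return MetricReport(
        wrj=totals[EdgeClass.REVERSING_JOIN],
        wfa=totals[EdgeClass.FEEDBACK_ARC],
        acw=acw(graph, lin, weighted=weighted_acw),
        counts=counts,
    )
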