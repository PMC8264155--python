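"""Reference linearizers used only for testing.

``naive_greedy`` is a literal transcription of the incremental algorithm
using explicit per-node orientation/position arrays and wholesale array
rewrites at every merge and reorder — slow but obviously faithful to the
insertion rules, and required to agree bit-for-bit with the optimized
implementation.

``exhaustive_best`` enumerates every orientation and order of a tiny graph
and returns the true optimum, the ground truth that the greedy heuristic is
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

from ..core import EdgeClass, Linearization, is_out_side
from ..graph import BidirectedGraph, Edge, Side


@dataclass
class OracleResult:
    lin: Linearization
    scores: tuple[float, float]  # (wrj, wfa)


def naive_greedy(graph: BidirectedGraph, edge_order: list[Edge]) -> Linearization:
    """Insertion algorithm with explicit arrays; same observable behavior
    as :func:`alibi.core.linearize` given the same edge order."""
    if len(graph) == 0:
        raise ValueError("cannot linearize an empty graph")
    nodes = graph.node_ids
    comp = {v: v for v in nodes}
    members = {v: [v] for v in nodes}
    orient = {v: 1 for v in nodes}
    pos = {v: 1 for v in nodes}
    forward: list[Edge] = []
    incident: dict[str, list[tuple[str, Edge]]] = {v: [] for v in nodes}
    classes: dict[Edge, EdgeClass] = {}

    def reverse_comp(c: str) -> None:
        n = len(members[c])
        for v in members[c]:
            pos[v] = n + 1 - pos[v]
            orient[v] = -orient[v]

    def concat(first: str, second: str) -> None:
        n1 = len(members[first])
        for v in members[second]:
            pos[v] += n1
            comp[v] = first
        members[first].extend(members.pop(second))

    def reachable(start: str, lo: int, hi: int, direction: str, abort_at):
        visited = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for w, _ in incident[x]:
                if w in visited:
                    continue
                if direction == "out":
                    ok = pos[x] < pos[w] <= hi
                else:
                    ok = lo <= pos[w] < pos[x]
                if ok:
                    if w == abort_at:
                        return True, visited
                    visited.add(w)
                    stack.append(w)
        return False, visited

    for edge in edge_order:
        (a, sa), (b, sb) = edge.endpoints()
        out_a = is_out_side(sa, orient[a])
        out_b = is_out_side(sb, orient[b])
        if comp[a] != comp[b]:
            if out_a == out_b:
                # both out: reverse b's component; both in: reverse a's
                reverse_comp(comp[b] if out_a else comp[a])
                out_a = is_out_side(sa, orient[a])
            if out_a:
                concat(comp[a], comp[b])
            else:
                concat(comp[b], comp[a])
            cls = EdgeClass.FORWARD_ARC
        elif out_a == out_b:
            cls = EdgeClass.REVERSING_JOIN
        elif a == b:
            cls = EdgeClass.FEEDBACK_ARC
        else:
            w_out, w_in = (a, b) if out_a else (b, a)
            if pos[w_out] < pos[w_in]:
                cls = EdgeClass.FORWARD_ARC
            else:
                lo, hi = pos[w_in], pos[w_out]
                hit, v_f = reachable(w_in, lo, hi, "out", w_out)
                if hit:
                    cls = EdgeClass.FEEDBACK_ARC
                else:
                    _, v_b = reachable(w_out, lo, hi, "in", None)
                    pooled = sorted(pos[v] for v in v_f | v_b)
                    ordered = sorted(v_b, key=pos.__getitem__) + sorted(
                        v_f, key=pos.__getitem__
                    )
                    for v, p in zip(ordered, pooled):
                        pos[v] = p
                    cls = EdgeClass.FORWARD_ARC
        if cls is EdgeClass.FORWARD_ARC:
            forward.append(edge)
            incident[a].append((b, edge))
            incident[b].append((a, edge))
        classes[edge] = cls

    # global order: components by smallest node declaration index
    comps = sorted(
        members.values(), key=lambda ms: min(graph.node_index(v) for v in ms)
    )
    order: dict[str, int] = {}
    offset = 0
    for ms in comps:
        for v in ms:
            order[v] = offset + pos[v]
        offset += len(ms)
    return Linearization(orient=dict(orient), order=order, classes=classes)


def exhaustive_best(graph: BidirectedGraph, objective: str = "lex") -> OracleResult:
    """True optimum over all 2^|V| orientations x |V|! orders (|V| <= 8).

    ``objective`` is ``"lex"`` for lexicographic (WRJ, WFA) or ``"sum"``
    for WRJ + WFA.  The first node's orientation is fixed to +1: metrics
    are invariant under global reversal, which halves the search space.
    Ties break by enumeration order.
    """
    n = len(graph)
    if n == 0:
        raise ValueError("empty graph")
    if n > 8:
        raise ValueError("exhaustive search guarded at |V| <= 8")
    if objective not in ("lex", "sum"):
        raise ValueError(f"unknown objective {objective!r}")
    nodes = graph.node_ids
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [
        (idx[e.a], e.side_a is Side.RIGHT, idx[e.b], e.side_b is Side.RIGHT, w)
        for e, w in graph.edges.items()
    ]

    best_key = None
    best = None
    for orients in product((1, -1), repeat=n - 1):
        a = (1,) + orients
        for perm in permutations(range(1, n + 1)):
            s_rj = s_fb = 0.0
            for ia, right_a, ib, right_b, w in edges:
                out_a = right_a == (a[ia] == 1)
                out_b = right_b == (a[ib] == 1)
                if out_a == out_b:
                    s_rj += w
                else:
                    p_out = perm[ia] if out_a else perm[ib]
                    p_in = perm[ib] if out_a else perm[ia]
                    if p_out >= p_in:
                        s_fb += w
            key = (s_rj, s_fb) if objective == "lex" else (s_rj + s_fb,)
            if best_key is None or key < best_key:
                best_key = key
                best = (a, perm)

    a, perm = best
    orient = {v: a[i] for v, i in idx.items()}
    order = {v: perm[i] for v, i in idx.items()}
    lin = Linearization(orient=orient, order=order, classes={})
    from ..metrics import classify_edges, wfa, wrj

    lin.classes = classify_edges(graph, lin)
    return OracleResult(lin=lin, scores=(wrj(graph, lin), wfa(graph, lin)))
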