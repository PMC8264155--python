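"""Incremental linearization of a bidirected graph (the ALIBI algorithm).

Linearizing a genome sequence graph means choosing a node orientation
``a : V -> {-1, +1}`` (which side of each node is its in-side) together with
a bijective position map ``ord : V -> {1..|V|}``.  Under a linearization
every edge falls in one of three classes:

* **forward arc** -- joins an out-side to an in-side, out-side node first;
* **feedback arc** -- out-side to in-side, but pointing backward in the order;
* **reversing join** -- joins two in-sides or two out-sides.

Paths through the graph are easiest to follow when their heavy edges are
forward arcs, so the algorithm inserts edges in descending weight order into
an initially edgeless graph, keeping every connected component linearized at
all times:

* an edge bridging two components is always made a forward arc, reversing
  one component wholesale if its sides disagree;
* within a component, a same-sided edge is forced to be a reversing join and
  an out->in edge pointing backward is forced to be a feedback arc exactly
  when a forward-arc path already runs the other way; otherwise a
  Pearce-Kelly style local reorder makes it forward.

Classifications, once made, are never invalidated by later insertions.
The component bookkeeping lives in :class:`~alibi.forest.LinearizationState`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .forest import LinearizationState
from .graph import BidirectedGraph, Edge, Side


class EdgeClass(Enum):
    FORWARD_ARC = "forward_arc"
    FEEDBACK_ARC = "feedback_arc"
    REVERSING_JOIN = "reversing_join"


@dataclass
class Linearization:
    """Result of linearizing a graph.

    ``orient`` maps nodes to {-1, +1} (+1 keeps the left side as in-side),
    ``order`` is a bijection onto {1..|V|}, and ``classes`` records the
    class assigned to every edge at its insertion; re-deriving classes from
    (orient, order) reproduces it.
    """

    orient: dict[str, int]
    order: dict[str, int]
    classes: dict[Edge, EdgeClass]


def is_out_side(side: Side, orientation: int) -> bool:
    """Whether ``side`` of a node with the given orientation is its out-side.

    With orientation +1 the right side is the out-side; -1 swaps the roles.
    """
    return (side is Side.RIGHT) == (orientation == 1)


def sort_edges(graph: BidirectedGraph) -> list[Edge]:
    """Edges in descending weight order; ties by canonical edge key."""
    return sorted(graph.edges, key=lambda e: (-graph.edges[e], e.key))


class IncrementalLinearizer:
    """Mutable algorithm state: the forest plus the forward-arc adjacency.

    The adjacency stores forward edges undirected; since a forward arc
    always runs from its lower- to its higher-positioned endpoint (component
    reversal flips sides and positions together), traversal direction is
    recovered from current positions and the adjacency survives reversals
    untouched.
    """

    def __init__(self, node_ids):
        self.state = LinearizationState(node_ids)
        self.adjacency: dict = {v: [] for v in self.state.ids}
        self.classes: dict[Edge, EdgeClass] = {}

    # -- classification ---------------------------------------------------

    def add_edge(self, edge: Edge) -> EdgeClass:
        if edge in self.classes:
            raise ValueError(f"edge {edge} already inserted")
        (a, sa), (b, sb) = edge.endpoints()
        ra, oa, pa = self.state.find(a)
        rb, ob, pb = self.state.find(b)
        out_a = is_out_side(sa, oa)
        out_b = is_out_side(sb, ob)

        if ra != rb:
            cls = self._bridge(edge, a, b, ra, rb, out_a, out_b)
        elif out_a == out_b:
            # same component, two in-sides or two out-sides: the component is
            # connected, so no re-orientation can fix just one endpoint.
            cls = EdgeClass.REVERSING_JOIN
        elif a == b:
            # out/in self edge: ord(v) < ord(v) is impossible
            cls = EdgeClass.FEEDBACK_ARC
        else:
            w_out, p_out = (a, pa) if out_a else (b, pb)
            w_in, p_in = (b, pb) if out_a else (a, pa)
            if p_out < p_in:
                cls = EdgeClass.FORWARD_ARC
            else:
                outcome = self.pearce_kelly_reorder(w_in, w_out)
                cls = (
                    EdgeClass.FEEDBACK_ARC
                    if outcome == "feedback"
                    else EdgeClass.FORWARD_ARC
                )
        if cls is EdgeClass.FORWARD_ARC:
            self.adjacency[a].append(b)
            self.adjacency[b].append(a)
        self.classes[edge] = cls
        return cls

    def _bridge(self, edge, a, b, ra, rb, out_a, out_b) -> EdgeClass:
        """Cross-component insertion: always realizable as a forward arc."""
        if out_a and not out_b:
            self.state.union_merge(ra, rb, reverse_b=False)
        elif out_b and not out_a:
            self.state.union_merge(rb, ra, reverse_b=False)
        elif out_a:  # both out-sides: reverse b's component, a's goes first
            self.state.union_merge(ra, rb, reverse_b=True)
        else:  # both in-sides: reverse a's component, which then goes first
            self.state.reverse_component(ra)
            self.state.union_merge(ra, rb, reverse_b=False)
        return EdgeClass.FORWARD_ARC

    # -- forward-arc traversal --------------------------------------------

    def forward_dfs_region(self, start, pos_lo: int, pos_hi: int, direction: str):
        """Nodes forward-reachable from/to ``start`` inside a position window.

        ``direction="out"`` collects nodes reachable from ``start`` along
        forward arcs with positions <= ``pos_hi``; ``direction="in"``
        collects nodes that reach ``start`` with positions >= ``pos_lo``.
        Forward arcs always increase position, so the window clamp prunes
        without losing reachability inside it.  ``start`` is included.
        """
        reached, visited = self._search(start, pos_lo, pos_hi, direction, None)
        assert not reached
        return visited

    def _search(self, start, pos_lo, pos_hi, direction, abort_at):
        find = self.state.find
        visited = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            px = find(x)[2]
            for w in self.adjacency[x]:
                if w in visited:
                    continue
                pw = find(w)[2]
                if direction == "out":
                    ok = px < pw <= pos_hi
                else:
                    ok = pos_lo <= pw < px
                if ok:
                    if w == abort_at:
                        return True, visited
                    visited.add(w)
                    stack.append(w)
        return False, visited

    # -- reorder -----------------------------------------------------------

    def pearce_kelly_reorder(self, in_node, out_node) -> str:
        """Try to move ``out_node`` before ``in_node`` within their component.

        Precondition: ``ord(in_node) < ord(out_node)`` and the new edge joins
        the out-side of ``out_node`` to the in-side of ``in_node``.  If a
        forward-arc path ``in_node ~> out_node`` exists the edge is doomed to
        be a feedback arc and the state is left untouched.  Otherwise the
        affected nodes

            V_F = {v : in_node ~> v,  pos(v) <= pos(out_node)}
            V_B = {v : v ~> out_node, pos(v) >= pos(in_node)}

        (necessarily disjoint) swap position pools: V_B takes the smallest
        of their pooled positions in its original relative order, V_F the
        rest, and every other node keeps its position.
        """
        r1, _, p_in = self.state.find(in_node)
        r2, _, p_out = self.state.find(out_node)
        if r1 != r2 or p_in >= p_out:
            raise ValueError("reorder precondition violated")
        reached, v_f = self._search(in_node, p_in, p_out, "out", out_node)
        if reached:
            return "feedback"
        _, v_b = self._search(out_node, p_in, p_out, "in", None)
        positions = {v: self.state.find(v)[2] for v in v_f | v_b}
        pooled = sorted(positions.values())
        ordered = sorted(v_b, key=positions.__getitem__) + sorted(
            v_f, key=positions.__getitem__
        )
        self.state.reposition(dict(zip(ordered, pooled)))
        return "reordered"


def linearize(graph: BidirectedGraph) -> Linearization:
    """Run the full incremental linearization on a weighted graph.

    Edges are inserted in descending weight order.  Components that remain
    separate (including isolated nodes) are concatenated in the final global
    order by their smallest node declaration index.
    """
    if len(graph) == 0:
        raise ValueError("cannot linearize an empty graph")
    lz = IncrementalLinearizer(graph.node_ids)
    for edge in sort_edges(graph):
        lz.add_edge(edge)
    return finalize(graph, lz)


def finalize(graph: BidirectedGraph, lz: IncrementalLinearizer) -> Linearization:
    """Concatenate per-component orders into one global linearization."""
    comps = lz.state.components()
    keyed = sorted(
        comps.values(), key=lambda members: min(graph.node_index(v) for v in members)
    )
    orient: dict[str, int] = {}
    order: dict[str, int] = {}
    offset = 0
    for members in keyed:
        for v in members:
            _, a, p = lz.state.find(v)
            orient[v] = a
            order[v] = offset + p
        offset += len(members)
    return Linearization(orient=orient, order=order, classes=dict(lz.classes))
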