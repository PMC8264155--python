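"""Shared builders: small graphs, and a shadow (explicit-array) forest."""

from __future__ import annotations

import pytest

from alibi.graph import BidirectedGraph, Edge, Side


def make_graph(n_nodes: int, edges, sequences=None) -> BidirectedGraph:
    """Graph over nodes "1".."n" from (a, side_a, b, side_b, weight) tuples."""
    g = BidirectedGraph()
    for i in range(n_nodes):
        node_id = str(i + 1)
        g.add_node(node_id, (sequences or {}).get(node_id, ""))
    for a, sa, b, sb, w in edges:
        g.add_edge(Edge.make(str(a), sa, str(b), sb), w)
    return g


def chain_graph(n: int, weight: float = 1.0) -> BidirectedGraph:
    """Directed chain 1 -> 2 -> ... -> n (out-side to in-side edges)."""
    return make_graph(
        n,
        [(i, Side.RIGHT, i + 1, Side.LEFT, weight) for i in range(1, n)],
    )


def cycle_graph(weights) -> BidirectedGraph:
    """Directed cycle over len(weights) nodes with the given edge weights."""
    n = len(weights)
    edges = [(i, Side.RIGHT, i % n + 1, Side.LEFT, w) for i, w in enumerate(weights, 1)]
    return make_graph(n, edges)


class ShadowForest:
    """Explicit-array reference for the augmented disjoint-set forest.

    Stores orientation and position per node directly and rewrites whole
    components at merges/reversals; used to validate the O(1)-attribute
    implementation over randomized operation sequences.
    """

    def __init__(self, ids):
        self.comp = {v: frozenset([v]) for v in ids}
        self.orient = {v: 1 for v in ids}
        self.pos = {v: 1 for v in ids}

    def find(self, v):
        return self.orient[v], self.pos[v]

    def same_component(self, u, v):
        return self.comp[u] is self.comp[v]

    def reverse_component(self, v):
        members = self.comp[v]
        n = len(members)
        for x in members:
            self.pos[x] = n + 1 - self.pos[x]
            self.orient[x] = -self.orient[x]

    def union_merge(self, a, b, reverse_b=False):
        assert self.comp[a] is not self.comp[b]
        if reverse_b:
            self.reverse_component(b)
        n1 = len(self.comp[a])
        merged = frozenset(self.comp[a] | self.comp[b])
        for x in self.comp[b]:
            self.pos[x] += n1
        for x in merged:
            self.comp[x] = merged

    def reposition(self, assignments):
        assert sorted(assignments.values()) == sorted(
            self.pos[v] for v in assignments
        )
        for v, p in assignments.items():
            self.pos[v] = p

    def partition(self):
        return {frozenset(c) for c in self.comp.values()}


def assert_states_match(state, shadow):
    """Real forest and shadow agree on partition, orientations, positions."""
    real = state.snapshot()
    comps = {}
    for v, (root, a, p) in real.items():
        comps.setdefault(root, set()).add(v)
        assert (a, p) == (shadow.orient[v], shadow.pos[v]), v
    assert {frozenset(c) for c in comps.values()} == shadow.partition()
    # positions within each component are exactly {1..size}
    for members in comps.values():
        positions = sorted(real[v][2] for v in members)
        assert positions == list(range(1, len(members) + 1))


@pytest.fixture
def fig2_graph():
    """6-node graph whose five consecutive cuts have widths 2, 3, 2, 2, 1."""
    pairs = [(1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (4, 5), (4, 6)]
    return make_graph(
        6, [(a, Side.RIGHT, b, Side.LEFT, 1.0) for a, b in pairs]
    )
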