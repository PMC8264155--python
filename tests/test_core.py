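"""The incremental insertion algorithm: case analysis, reordering, invariants."""

import networkx as nx
import pytest

from alibi.core import (
    EdgeClass,
    IncrementalLinearizer,
    finalize,
    linearize,
    sort_edges,
)
from alibi.graph import Edge, Side
from alibi.metrics import classify_edges, wfa, wrj
from alibi.synthetic import generate_random_bidirected

from conftest import chain_graph, cycle_graph, make_graph


def edge(a, sa, b, sb):
    return Edge.make(str(a), sa, str(b), sb)


class TestSortEdges:
    def test_descending_by_weight(self):
        g = cycle_graph([3, 5, 2])
        assert [g.edges[e] for e in sort_edges(g)] == [5, 3, 2]

    def test_ties_break_by_canonical_key(self):
        g = make_graph(
            3,
            [(2, Side.RIGHT, 3, Side.LEFT, 1.0), (1, Side.RIGHT, 2, Side.LEFT, 1.0)],
        )
        assert [e.a for e in sort_edges(g)] == ["1", "2"]

    def test_empty(self):
        assert sort_edges(make_graph(2, [])) == []


class TestAddEdgeCases:
    def test_bridge_mixed_sides_keeps_orientations(self):
        lz = IncrementalLinearizer(["u", "v"])
        assert lz.add_edge(Edge.make("u", Side.RIGHT, "v", Side.LEFT)) is EdgeClass.FORWARD_ARC
        assert lz.state.find("u")[1:] == (1, 1)
        assert lz.state.find("v")[1:] == (1, 2)

    def test_bridge_same_sides_reverses_one_component(self):
        lz = IncrementalLinearizer(["u", "v"])
        assert lz.add_edge(Edge.make("u", Side.RIGHT, "v", Side.RIGHT)) is EdgeClass.FORWARD_ARC
        orients = {v: lz.state.find(v)[1] for v in "uv"}
        assert sorted(orients.values()) == [-1, 1]
        # the out-side endpoint under the final orientation comes first
        (_, _, pu), (_, _, pv) = lz.state.find("u"), lz.state.find("v")
        assert {pu, pv} == {1, 2}

    def test_feedback_when_forward_path_exists(self):
        lz = IncrementalLinearizer(["u", "v", "w"])
        lz.add_edge(edge("u", Side.RIGHT, "v", Side.LEFT))
        lz.add_edge(edge("v", Side.RIGHT, "w", Side.LEFT))
        back = Edge.make("w", Side.RIGHT, "u", Side.LEFT)
        assert lz.add_edge(back) is EdgeClass.FEEDBACK_ARC

    def test_reversing_join_within_component(self):
        lz = IncrementalLinearizer(["u", "v"])
        lz.add_edge(edge("u", Side.RIGHT, "v", Side.LEFT))
        same_sided = Edge.make("u", Side.RIGHT, "v", Side.RIGHT)
        assert lz.add_edge(same_sided) is EdgeClass.REVERSING_JOIN

    def test_out_in_self_edge_is_feedback(self):
        lz = IncrementalLinearizer(["v"])
        assert lz.add_edge(Edge.make("v", Side.RIGHT, "v", Side.LEFT)) is EdgeClass.FEEDBACK_ARC

    def test_same_side_self_edge_is_reversing_join(self):
        lz = IncrementalLinearizer(["v"])
        assert lz.add_edge(Edge.make("v", Side.LEFT, "v", Side.LEFT)) is EdgeClass.REVERSING_JOIN

    def test_duplicate_insertion_rejected(self):
        lz = IncrementalLinearizer(["u", "v"])
        e = edge("u", Side.RIGHT, "v", Side.LEFT)
        lz.add_edge(e)
        with pytest.raises(ValueError):
            lz.add_edge(e)


class TestForwardDfsRegion:
    def chain(self):
        lz = IncrementalLinearizer(["a", "b", "c"])
        lz.add_edge(Edge.make("a", Side.RIGHT, "b", Side.LEFT))
        lz.add_edge(Edge.make("b", Side.RIGHT, "c", Side.LEFT))
        return lz

    def test_full_region(self):
        assert self.chain().forward_dfs_region("a", 1, 3, "out") == {"a", "b", "c"}

    def test_region_clamp(self):
        assert self.chain().forward_dfs_region("a", 1, 2, "out") == {"a", "b"}

    def test_inbound_direction(self):
        assert self.chain().forward_dfs_region("c", 2, 3, "in") == {"b", "c"}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_reachability(self, seed):
        g = generate_random_bidirected(14, 22, "uniform", seed=seed)
        lz = IncrementalLinearizer(g.node_ids)
        for e in sort_edges(g):
            lz.add_edge(e)
        pos = {v: lz.state.find(v)[2] for v in g.node_ids}
        comp = {v: lz.state.find(v)[0] for v in g.node_ids}
        dg = nx.DiGraph()
        dg.add_nodes_from(g.node_ids)
        for e, cls in lz.classes.items():
            if cls is EdgeClass.FORWARD_ARC:
                u, v = (e.a, e.b) if pos[e.a] < pos[e.b] else (e.b, e.a)
                dg.add_edge(u, v)
        for start in g.node_ids:
            hi = max(pos[v] for v in g.node_ids if comp[v] == comp[start])
            expected = {
                v
                for v in nx.descendants(dg, start) | {start}
                if pos[v] <= hi and comp[v] == comp[start]
            }
            assert lz.forward_dfs_region(start, 1, hi, "out") == expected


class TestPearceKellyReorder:
    def build_square(self):
        # x->p and q->y, joined by p->y: order x(1) p(2) q(3) y(4)
        lz = IncrementalLinearizer(["p", "q", "x", "y"])
        lz.add_edge(Edge.make("x", Side.RIGHT, "p", Side.LEFT))
        lz.add_edge(Edge.make("q", Side.RIGHT, "y", Side.LEFT))
        lz.add_edge(Edge.make("p", Side.RIGHT, "y", Side.LEFT))
        assert {v: lz.state.find(v)[2] for v in "xpqy"} == {
            "x": 1, "p": 2, "q": 3, "y": 4,
        }
        return lz

    def test_two_node_swap(self):
        lz = self.build_square()
        # new edge out(q)-in(p): V_F = {p}, V_B = {q}; swap their positions
        assert lz.add_edge(Edge.make("q", Side.RIGHT, "p", Side.LEFT)) is EdgeClass.FORWARD_ARC
        assert {v: lz.state.find(v)[2] for v in "xpqy"} == {
            "x": 1, "q": 2, "p": 3, "y": 4,
        }

    def test_feedback_leaves_state_unchanged(self):
        lz = self.build_square()
        before = lz.state.snapshot()
        # p ~> y via the forward arc, so out(y)-in(p) must be feedback
        assert lz.add_edge(Edge.make("y", Side.RIGHT, "p", Side.LEFT)) is EdgeClass.FEEDBACK_ARC
        assert lz.state.snapshot() == before

    def test_precondition_violation_raises(self):
        lz = self.build_square()
        with pytest.raises(ValueError):
            lz.pearce_kelly_reorder("y", "x")  # ord order is wrong way round


class TestLinearize:
    def test_chain_is_perfect(self):
        g = chain_graph(6)
        lin = linearize(g)
        assert wrj(g, lin) == 0 and wfa(g, lin) == 0
        assert sorted(lin.order.values()) == list(range(1, 7))

    def test_three_cycle_drops_lightest_edge(self):
        g = cycle_graph([5, 3, 2])
        lin = linearize(g)
        assert wrj(g, lin) == 0 and wfa(g, lin) == 2
        heavy = edge(1, Side.RIGHT, 2, Side.LEFT)
        light = edge(3, Side.RIGHT, 1, Side.LEFT)
        assert lin.classes[heavy] is EdgeClass.FORWARD_ARC
        assert lin.classes[light] is EdgeClass.FEEDBACK_ARC

    def test_edgeless_graph_keeps_declaration_order(self):
        g = make_graph(3, [])
        lin = linearize(g)
        assert lin.order == {"1": 1, "2": 2, "3": 3}
        assert set(lin.orient.values()) == {1}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            linearize(make_graph(0, []))

    def test_singletons_appended_by_declaration_index(self):
        g = make_graph(4, [(2, Side.RIGHT, 3, Side.LEFT, 1.0)])
        lin = linearize(g)
        assert lin.order["1"] == 1
        assert lin.order["2"] == 2 and lin.order["3"] == 3
        assert lin.order["4"] == 4


class TestInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_classification_coherence_and_acyclicity(self, seed):
        g = generate_random_bidirected(20, 40, "uniform", seed=100 + seed, allow_self_edges=True)
        lin = linearize(g)
        assert classify_edges(g, lin) == lin.classes
        # forward arcs respect the order: a topological-order invariant
        for e, cls in lin.classes.items():
            if cls is EdgeClass.FORWARD_ARC:
                assert lin.order[e.a] != lin.order[e.b]

    @pytest.mark.parametrize("seed", range(10))
    def test_cross_component_edges_always_forward(self, seed):
        g = generate_random_bidirected(18, 30, "unit", seed=200 + seed)
        lz = IncrementalLinearizer(g.node_ids)
        for e in sort_edges(g):
            cross = lz.state.find(e.a)[0] != lz.state.find(e.b)[0]
            cls = lz.add_edge(e)
            if cross:
                assert cls is EdgeClass.FORWARD_ARC
        lin = finalize(g, lz)
        assert sorted(lin.order.values()) == list(range(1, len(g) + 1))
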