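"""Bidirected graph data model and GFA1 input/output.

A genome sequence graph is a bidirected graph: every node has a *left* and a
*right* side (the 5' and 3' ends of its DNA label) and each edge endpoint
attaches to one specific side.  Directed graphs are the special case in which
every edge joins a right side to a left side.  A collection of genome paths
traverses the graph; the number of times the paths cross an edge defines the
edge's weight, which drives the greedy linearization order.

GFA1 conventions used here:

* ``S`` lines declare nodes (segments) with an optional DNA label.
* An ``L`` line ``L a oa b ob`` attaches to the *right* side of ``a`` when
  ``oa`` is ``+`` and to its *left* side when ``oa`` is ``-``; symmetrically
  it attaches to the *left* side of ``b`` for ``+`` and the *right* side for
  ``-``.  The two readings of one bidirected edge (``L a + b +`` and
  ``L b - a -``) therefore collapse to the same canonical edge.
* ``P`` lines declare genome paths as comma-separated oriented visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GFAError(ValueError):
    """Malformed GFA document or graph/path inconsistency."""


class Side(IntEnum):
    """One of the two ends of a node; LEFT is the 5' end of the label."""

    LEFT = 0
    RIGHT = 1

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


@dataclass(frozen=True)
class Edge:
    """A canonical bidirected edge: endpoints sorted by (node id, side).

    ``(v, s, v', s')`` and ``(v', s', v, s)`` denote the same edge; use
    :meth:`make` to construct the canonical representative.  Self edges
    (same node, same or different sides) are representable.
    """

    a: str
    side_a: Side
    b: str
    side_b: Side

    @staticmethod
    def make(a: str, side_a: Side, b: str, side_b: Side) -> "Edge":
        if (a, side_a) <= (b, side_b):
            return Edge(a, side_a, b, side_b)
        return Edge(b, side_b, a, side_a)

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.a, int(self.side_a), self.b, int(self.side_b))

    def endpoints(self) -> tuple[tuple[str, Side], tuple[str, Side]]:
        return (self.a, self.side_a), (self.b, self.side_b)

    def is_self(self) -> bool:
        return self.a == self.b


@dataclass
class GenomePath:
    """A named genome traversal: oriented node visits, GFA strand symbols."""

    name: str
    visits: list[tuple[str, str]]  # (node id, '+' or '-')

    def adjacencies(self) -> Iterable[Edge]:
        """Canonical edges induced by consecutive visits.

        A visit on ``+`` strand exits through the node's right side and a
        ``-`` visit through its left side; entry is the mirror image.
        """
        for (u, ou), (v, ov) in zip(self.visits, self.visits[1:]):
            su = Side.RIGHT if ou == "+" else Side.LEFT
            sv = Side.LEFT if ov == "+" else Side.RIGHT
            yield Edge.make(u, su, v, sv)


@dataclass
class BidirectedGraph:
    """Nodes with DNA labels, canonical weighted edges, and genome paths."""

    sequences: dict[str, str] = field(default_factory=dict)
    edges: dict[Edge, float] = field(default_factory=dict)
    paths: list[GenomePath] = field(default_factory=list)

    # dense integer index per node, in declaration order (determinism)
    _index: dict[str, int] = field(default_factory=dict)

    def add_node(self, node_id: str, sequence: str = "") -> None:
        if node_id in self.sequences:
            raise GFAError(f"duplicate segment id {node_id!r}")
        self.sequences[node_id] = sequence
        self._index[node_id] = len(self._index)

    def add_edge(self, edge: Edge, weight: float = 1.0) -> None:
        for v, _ in edge.endpoints():
            if v not in self.sequences:
                raise GFAError(f"edge references unknown segment {v!r}")
        if edge not in self.edges:
            self.edges[edge] = weight

    def node_index(self, node_id: str) -> int:
        return self._index[node_id]

    @property
    def node_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}, case-preserving."""
    for i, c in enumerate(seq):
        if c not in "ACGTNacgtn":
            raise ValueError(f"illegal DNA character {c!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def _fields(line: str) -> list[str]:
    # GFA is tab-separated; tolerate space-separated toy inputs.
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1:
        parts = line.split()
    return parts


def _link_sides(strand_a: str, strand_b: str, line: str) -> tuple[Side, Side]:
    if strand_a not in "+-" or strand_b not in "+-":
        raise GFAError(f"malformed strand symbol in line: {line!r}")
    sa = Side.RIGHT if strand_a == "+" else Side.LEFT
    sb = Side.LEFT if strand_b == "+" else Side.RIGHT
    return sa, sb


def parse_gfa(text: str, weight_tag: str | None = None) -> BidirectedGraph:
    """Parse a GFA1 document (S/L/P lines) into a :class:`BidirectedGraph`.

    Edge weights are derived from path traversal counts via
    :func:`compute_edge_weights`; if ``weight_tag`` names a numeric L-line
    tag (e.g. ``"RC"``), its values override path-derived weights.

    GFA2 documents and W lines are rejected; other record types are skipped
    with a logged warning.  Dangling segment references are errors.
    """
    graph = BidirectedGraph()
    links: list[tuple[Edge, float | None]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        parts = _fields(raw)
        rec = parts[0]
        if rec == "H":
            for tag in parts[1:]:
                if tag.startswith("VN:Z:2"):
                    raise GFAError("GFA2 documents are not supported (GFA1 only)")
        elif rec == "S":
            if len(parts) < 2:
                raise GFAError(f"line {lineno}: S line missing segment name")
            seq = parts[2] if len(parts) > 2 else "*"
            graph.add_node(parts[1], "" if seq == "*" else seq)
        elif rec == "L":
            if len(parts) < 5:
                raise GFAError(f"line {lineno}: truncated L line: {raw!r}")
            a, oa, b, ob = parts[1:5]
            for v in (a, b):
                if v not in graph.sequences:
                    raise GFAError(
                        f"line {lineno}: L line references unknown segment {v!r}"
                    )
            sa, sb = _link_sides(oa, ob, raw)
            tag_weight = None
            if weight_tag is not None:
                for tag in parts[5:]:
                    name, _, rest = tag.partition(":")
                    if name == weight_tag:
                        tag_weight = float(rest.split(":")[-1])
            links.append((Edge.make(a, sa, b, sb), tag_weight))
        elif rec == "P":
            if len(parts) < 3:
                raise GFAError(f"line {lineno}: truncated P line: {raw!r}")
            visits = []
            for item in parts[2].split(","):
                node, strand = item[:-1], item[-1]
                if strand not in "+-":
                    raise GFAError(
                        f"line {lineno}: malformed path step {item!r}"
                    )
                if node not in graph.sequences:
                    raise GFAError(
                        f"line {lineno}: P line references unknown segment {node!r}"
                    )
                visits.append((node, strand))
            graph.paths.append(GenomePath(parts[1], visits))
        elif rec == "W":
            raise GFAError("W lines (GFA1.1 walks) are not supported")
        else:
            log.warning("skipping unsupported GFA record type %r", rec)

    overrides = {e: w for e, w in links if w is not None}
    for edge, _ in links:
        graph.add_edge(edge, 1.0)
    compute_edge_weights(graph)
    for edge, w in overrides.items():
        graph.edges[edge] = w
    return graph


def compute_edge_weights(graph: BidirectedGraph) -> BidirectedGraph:
    """Set each edge weight to its total path traversal count.

    With no paths at all every edge keeps weight 1 (uniform greedy order);
    when paths exist, edges traversed by no path get weight 0.  A path
    adjacency with no matching edge is a validation error.
    """
    if not graph.paths:
        for edge in graph.edges:
            graph.edges[edge] = 1.0
        return graph
    for edge in graph.edges:
        graph.edges[edge] = 0.0
    for path in graph.paths:
        for edge in path.adjacencies():
            if edge not in graph.edges:
                raise GFAError(
                    f"path {path.name!r} traverses missing edge "
                    f"{edge.a}:{edge.side_a.name}--{edge.b}:{edge.side_b.name}"
                )
            graph.edges[edge] += 1.0
    return graph


def _strand_for(side: Side, flipped: bool, source: bool) -> str:
    # A flipped node swaps the meaning of its sides.
    if flipped:
        side = side.other
    if source:
        return "+" if side is Side.RIGHT else "-"
    return "+" if side is Side.LEFT else "-"


def write_gfa(graph: BidirectedGraph, lin=None) -> str:
    """Serialize to GFA1.  With a linearization, re-orient and re-order.

    Nodes are emitted in increasing position; a node with orientation -1 is
    written with its reverse-complemented label, and every L/P reference to
    it has its strand flipped, so each path spells the identical DNA string
    before and after the rewrite.
    """
    if lin is not None:
        missing = [v for v in graph.sequences if v not in lin.order]
        if missing:
            raise ValueError(f"linearization misses nodes: {missing[:5]}")
        node_order = sorted(graph.sequences, key=lambda v: lin.order[v])
        flipped = {v for v in graph.sequences if lin.orient[v] == -1}
    else:
        node_order = list(graph.sequences)
        flipped = set()

    out = ["H\tVN:Z:1.0"]
    for v in node_order:
        seq = graph.sequences[v]
        if v in flipped and seq:
            seq = reverse_complement(seq)
        out.append(f"S\t{v}\t{seq or '*'}")
    for edge in sorted(graph.edges, key=lambda e: e.key):
        (a, sa), (b, sb) = edge.endpoints()
        oa = _strand_for(sa, a in flipped, source=True)
        ob = _strand_for(sb, b in flipped, source=False)
        out.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M")
    for path in graph.paths:
        steps = []
        for node, strand in path.visits:
            if node in flipped:
                strand = "+" if strand == "-" else "-"
            steps.append(f"{node}{strand}")
        out.append(f"P\t{path.name}\t{','.join(steps)}\t*")
    return "\n".join(out) + "\n"


def spell_path(graph: BidirectedGraph, path: GenomePath) -> str:
    """DNA string represented by a path: concatenated oriented node labels."""
    pieces = []
    for node, strand in path.visits:
        seq = graph.sequences[node]
        pieces.append(seq if strand == "+" else reverse_complement(seq))
    return "".join(pieces)
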