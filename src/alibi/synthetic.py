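"""Synthetic pangenome-graph generator with known ground truth.

Emulates the standard simulation protocol for evaluating graph
linearization: take a reference fragment, derive a set of rearranged
genomes by applying structural variants (deletions, insertions, inversions
and tandem duplications of fixed per-type lengths), and build the sequence
graph those genomes induce.  Because every breakpoint is known exactly, the
graph is constructed directly by segmenting the reference at the union of
all breakpoints — no alignment heuristics — which makes path spelling an
exact, byte-level correctness check: concatenating oriented node labels
along each genome's path must reproduce that genome's mutated sequence.

Also provides a seeded random bidirected-graph generator used to fuzz the
linearizer against its reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import BidirectedGraph, Edge, GenomePath, Side, compute_edge_weights, reverse_complement

VARIANT_KINDS = ("deletion", "insertion", "inversion", "duplication")

#: Per-type variant lengths (bp): deletion, insertion, inversion, duplication.
DEFAULT_LENGTHS = {"deletion": 20, "insertion": 20, "inversion": 200, "duplication": 500}


@dataclass(frozen=True)
class VariantSpec:
    """One structural variant on the reference.

    ``ref_start`` is 1-based.  Deletion/inversion/duplication cover the
    reference interval [ref_start, ref_start+length-1]; an insertion places
    ``sequence`` immediately before position ``ref_start`` (a zero-length
    reference interval).  Duplications are tandem.
    """

    kind: str
    ref_start: int
    length: int
    sequence: str = ""

    def interval(self) -> tuple[int, int]:
        """Occupied reference interval, 0-based half-open."""
        s = self.ref_start - 1
        if self.kind == "insertion":
            return s, s
        return s, s + self.length


@dataclass
class SimConfig:
    """Simulation conditions.

    Defaults mirror the evaluation protocol this generator emulates: a
    37287 bp reference, 5-11 variants of each type per genome (default 5),
    10 rearranged genomes, variant lengths 20/20/200/500 bp.
    """

    seed: int
    ref_length: int = 37287
    variants_per_type: int = 5
    n_genomes: int = 10
    lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LENGTHS))
    types: Sequence[str] = VARIANT_KINDS
    shared_loci: bool = False
    include_reference: bool = True
    #: maximum reference-segment label length, like the node-size cap of
    #: graph constructors; keeps the variant-free graph a proper chain
    max_node_length: int = 32

    def __post_init__(self):
        if self.ref_length <= 0 or self.n_genomes <= 0 or self.variants_per_type < 0:
            raise ValueError("ref_length and n_genomes must be positive, k >= 0")
        for t in self.types:
            if t not in VARIANT_KINDS:
                raise ValueError(f"unknown variant type {t!r}")


@dataclass
class SimResult:
    reference: str
    genomes: list[list[VariantSpec]]  # per-genome variants, ref-sorted


class PlacementError(RuntimeError):
    """Variants could not be placed without overlap; lower k or lengths."""


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _place(
    rng: np.random.Generator,
    config: SimConfig,
    occupied: list[tuple[int, int]],
    kind: str,
) -> VariantSpec:
    length = config.lengths[kind]
    for _ in range(1000):
        if kind == "insertion":
            start0 = int(rng.integers(1, config.ref_length))
            lo, hi = start0, start0
        else:
            if length > config.ref_length:
                break
            start0 = int(rng.integers(0, config.ref_length - length + 1))
            lo, hi = start0, start0 + length
        # require a >= 1 bp gap to every other variant so breakpoints of
        # different variants in one genome never coincide
        if all(hi + 1 <= a or b + 1 <= lo for a, b in occupied):
            occupied.append((lo, hi))
            seq = _random_dna(rng, length) if kind == "insertion" else ""
            return VariantSpec(kind, start0 + 1, length, seq)
    raise PlacementError(
        f"could not place a {kind} of length {length} without overlap; "
        "reduce variants_per_type or lengths"
    )


def simulate_genomes(config: SimConfig) -> SimResult:
    """Draw a random reference and per-genome variant lists, reproducibly."""
    rng = np.random.default_rng(config.seed)
    reference = _random_dna(rng, config.ref_length)
    genomes: list[list[VariantSpec]] = []
    if config.shared_loci:
        # one pool of 2k variants per type; each genome samples k of them
        pool: list[VariantSpec] = []
        occupied: list[tuple[int, int]] = []
        for kind in config.types:
            for _ in range(2 * config.variants_per_type):
                pool.append(_place(rng, config, occupied, kind))
        for _ in range(config.n_genomes):
            chosen: list[VariantSpec] = []
            for kind in config.types:
                of_kind = [v for v in pool if v.kind == kind]
                picks = rng.choice(
                    len(of_kind), size=config.variants_per_type, replace=False
                )
                chosen.extend(of_kind[i] for i in sorted(picks))
            genomes.append(sorted(chosen, key=lambda v: v.ref_start))
    else:
        for _ in range(config.n_genomes):
            occupied = []
            variants: list[VariantSpec] = []
            for kind in config.types:
                for _ in range(config.variants_per_type):
                    variants.append(_place(rng, config, occupied, kind))
            genomes.append(sorted(variants, key=lambda v: v.ref_start))
    return SimResult(reference=reference, genomes=genomes)


def apply_variants(reference: str, variants: Sequence[VariantSpec]) -> str:
    """Mutated genome string: apply variants right-to-left on the reference."""
    seq = reference
    for var in sorted(variants, key=lambda v: v.ref_start, reverse=True):
        s = var.ref_start - 1
        e = s + var.length
        if var.kind == "deletion":
            seq = seq[:s] + seq[e:]
        elif var.kind == "insertion":
            seq = seq[:s] + var.sequence + seq[s:]
        elif var.kind == "inversion":
            seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
        elif var.kind == "duplication":
            seq = seq[: e] + seq[s:e] + seq[e:]
        else:
            raise ValueError(f"unknown variant kind {var.kind!r}")
    return seq


def build_graph(
    reference: str,
    per_genome_variants: Sequence[Sequence[VariantSpec]],
    include_reference: bool = True,
    max_node_length: int = 32,
) -> BidirectedGraph:
    """Exact sequence graph induced by the reference and variant genomes.

    The reference is segmented at the union of all breakpoints across
    genomes, then further chunked so no segment label exceeds
    ``max_node_length`` (graph constructors cap node size the same way, and
    a variant-free simulation should still yield a chain, not one node).
    Each segment becomes a node, each distinct insertion (keyed by position
    and sequence) becomes a node, and every genome — plus, optionally, the
    reference itself — becomes a path.  Edges are exactly the path
    adjacencies; weights are path traversal counts.
    """
    if max_node_length <= 0:
        raise ValueError("max_node_length must be positive")
    n = len(reference)
    cuts = {0, n}
    for variants in per_genome_variants:
        for var in variants:
            lo, hi = var.interval()
            cuts.update((lo, hi))
    bounds = sorted(cuts)
    chunked = []
    for lo, hi in zip(bounds, bounds[1:]):
        chunked.extend(range(lo, hi, max_node_length))
    bounds = sorted(set(chunked) | {n})
    graph = BidirectedGraph()
    seg_index_at: dict[int, int] = {}
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        graph.add_node(str(i + 1), reference[lo:hi])
        seg_index_at[lo] = i
    seg_index_at[n] = len(bounds) - 1
    n_segments = len(bounds) - 1

    ins_nodes: dict[tuple[int, str], str] = {}

    def insertion_node(var: VariantSpec) -> str:
        key = (var.ref_start, var.sequence)
        if key not in ins_nodes:
            node_id = str(len(graph) + 1)
            graph.add_node(node_id, var.sequence)
            ins_nodes[key] = node_id
        return ins_nodes[key]

    paths: list[GenomePath] = []
    if include_reference:
        paths.append(
            GenomePath("ref", [(str(i + 1), "+") for i in range(n_segments)])
        )
    for g, variants in enumerate(per_genome_variants):
        visits: list[tuple[str, str]] = []
        cursor = 0  # next reference segment index to emit
        for var in sorted(variants, key=lambda v: v.ref_start):
            lo, hi = var.interval()
            si, sj = seg_index_at[lo], seg_index_at[hi]
            visits.extend((str(i + 1), "+") for i in range(cursor, si))
            if var.kind == "deletion":
                pass  # skip segments si..sj-1
            elif var.kind == "insertion":
                visits.append((insertion_node(var), "+"))
            elif var.kind == "inversion":
                visits.extend((str(i + 1), "-") for i in range(sj - 1, si - 1, -1))
            elif var.kind == "duplication":
                block = [(str(i + 1), "+") for i in range(si, sj)]
                visits.extend(block + block)
            cursor = sj
        visits.extend((str(i + 1), "+") for i in range(cursor, n_segments))
        paths.append(GenomePath(f"genome{g + 1}", visits))

    graph.paths = paths
    for path in paths:
        for edge in path.adjacencies():
            graph.add_edge(edge)
    return compute_edge_weights(graph)


def generate(config: SimConfig) -> tuple[BidirectedGraph, SimResult]:
    """Full protocol: simulate genomes, then build their sequence graph."""
    sim = simulate_genomes(config)
    graph = build_graph(
        sim.reference,
        sim.genomes,
        include_reference=config.include_reference,
        max_node_length=config.max_node_length,
    )
    return graph, sim


def generate_random_bidirected(
    n_nodes: int,
    n_edges: int,
    weight_law: str = "unit",
    seed: int = 0,
    allow_self_edges: bool = False,
) -> BidirectedGraph:
    """Seeded random bidirected graph (uniform endpoints and sides).

    Duplicate draws collapse onto the canonical edge set, so the graph may
    end up with fewer than ``n_edges`` edges on dense requests.
    ``weight_law`` is ``"unit"`` (all 1) or ``"uniform"`` (integers 1..10).
    """
    if n_nodes <= 0 or n_edges < 0:
        raise ValueError("need n_nodes >= 1, n_edges >= 0")
    rng = np.random.default_rng(seed)
    graph = BidirectedGraph()
    for i in range(n_nodes):
        graph.add_node(str(i + 1))
    attempts = 0
    while len(graph.edges) < n_edges and attempts < 50 * n_edges + 100:
        attempts += 1
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v and not allow_self_edges:
            continue
        su, sv = rng.integers(0, 2, size=2)
        edge = Edge.make(str(u + 1), Side(int(su)), str(v + 1), Side(int(sv)))
        if edge in graph.edges:
            continue
        if weight_law == "unit":
            w = 1.0
        elif weight_law == "uniform":
            w = float(rng.integers(1, 11))
        else:
            raise ValueError(f"unknown weight law {weight_law!r}")
        graph.add_edge(edge, w)
    return graph
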