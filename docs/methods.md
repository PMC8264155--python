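# Methods

## Model and procedure

A bidirected graph `(V, E)` has edges `(v, s, v′, s′)` with `s, s′ ∈ {left,
right}`. A linearization is a pair `(a, ord)`: `a : V → {−1, +1}` labels each
node's sides as in-/out-side (`a(v) = 1` makes the left side the in-side) and
`ord : V → {1..|V|}` is a bijection. Edge classes follow from the
definitions: reversing joins connect two in- or two out-sides; among the
remaining (out→in) edges, forward arcs have the out-side node first and
feedback arcs do not. The target of the heuristic is to keep the total
weight of reversing joins (WRJ) and feedback arcs (WFA) small; weights are
genome-path traversal counts, so heavy edges are the ones real genomes
follow often.

Edges are inserted in descending weight order (ties broken by canonical edge
key, ascending, for reproducibility) into an edgeless graph whose nodes start
as singleton components with orientation +1 and position 1. The insertion
rules are forced by two facts about already-linearized components:

1. *Bridging edges can always be forward.* Concatenating the two component
   orders — reversing one component first when the edge joins two like
   sides — realizes the new edge as a forward arc without reclassifying any
   existing edge. Reversal maps positions `p → |V₂|+1−p` and negates
   orientations; concatenation then places the out-side endpoint's component
   on positions `{1..|V₁|}` and the other on `{|V₁|+1..|V₁|+|V₂|}`.
2. *Within a component, classification is forced exactly when it must be.*
   A same-sided edge cannot be fixed by re-orienting one endpoint (the
   component is connected) → reversing join. An out→in edge pointing
   backward is a feedback arc precisely when a forward-arc path runs from
   its in-side node `v₁` to its out-side node `v₂`; such a path fixes their
   relative order. Otherwise the affected window `[ord(v₁), ord(v₂)]` is
   repaired in the dynamic-topological-sort style of Pearce and Kelly: with
   `V_F = {v : v₁ ⇝ v, ord(v) ≤ ord(v₂)}` and `V_B = {v : v ⇝ v₂, ord(v) ≥
   ord(v₁)}` (disjoint, else `v₁ ⇝ v₂`), the pooled positions of `V_F ∪ V_B`
   are reassigned so all of `V_B` precedes all of `V_F`, preserving relative
   order inside each set; every other node keeps its position.

Classifications recorded at insertion are never invalidated later; the test
suite re-derives every class from the final `(a, ord)` and checks equality.
The final global order concatenates components (including isolated nodes) by
their smallest node declaration index — the method only ever defines order
within components, so some deterministic inter-component rule is needed and
declaration order is the least surprising.

## Data structure

Orientations and positions are maintained in a union-find forest (union by
rank, path compression) whose entries carry three attributes relative to the
tree parent: `orient` (±1), `shift` (inherited by descendants) and
`reorder_shift` (not inherited). A node's actual orientation is the product
of `orient` over it and its ancestors; its actual position is `Σ shift(u) ·
A(u)` over proper ancestors `u` plus `(shift + reorder_shift) · A(v)`.
Consequences used throughout:

* *Compression fold.* Re-parenting `c` (attributes `o_c, s_c`) from a parent
  `p` that is already a direct child of the root gives `o_c ← o_c·o_p`,
  `s_c ← s_c + s_p·o_c`, `reorder_shift` untouched. This preserves every
  node's observable values, including descendants of `c`.
* *O(1) merge and reversal.* Reversing a component edits only its root
  (`orient ← −A`, `shift ← (n+1 − shift·A)·(−A)`); concatenation edits the
  root of whichever component loses the rank comparison, with a sign/offset
  fix-up so the merged order never depends on which root won.
* `reposition` changes only `reorder_shift` of the listed nodes, so a
  Pearce–Kelly repair never displaces descendants in the forest.

Positions are Python integers (arbitrary precision; internal shifts can be
negative and large after long reversal chains). Each component's positions
are kept on exactly `{1..size}` — the structure only needs *some* contiguous
interval, but pinning it at 1 makes every state enumerable in tests. The
forest counts attribute writes and compression steps; a test asserts a merge
costs at most 6 attribute writes beyond the finds that locate the roots.

Forward arcs are stored undirected in an adjacency list: a forward arc
always points from its lower- to its higher-positioned endpoint (component
reversal flips sides and positions together), so traversal direction is
recomputed from positions and the adjacency survives reversals untouched.
Forward-path existence checking is fused into the `V_F` search (abort on
reaching `v₂`, discarding the visited set) — forward arcs strictly increase
position, so clamping the search to the affected window loses nothing.

## Degenerate inputs and tie-breaks

* Self-edges: out/in self-edge → feedback arc (`ord(v) < ord(v)` is
  impossible); same-sided self-edge → reversing join. These are the only
  classifications consistent with the definitions.
* Same-sided bridging edges: both-out reverses the second canonical
  endpoint's component, both-in the first's; either way the component whose
  endpoint is an out-side after reversal goes first. Any fixed rule is
  valid; this one is shared verbatim with the naive reference so the two
  implementations agree bit-for-bit.
* Graphs with no paths at all get unit weights on every edge; when paths
  exist, uncovered edges get weight 0 and are inserted last but still
  classified. A numeric L-line tag can override path-derived weights for
  graphs distributed without P lines (off by default).
* Empty graphs are rejected; edgeless nodes remain singletons appended in
  declaration order.

## Metrics

WRJ and WFA sum edge weights per class, derived purely from `(a, ord)`. ACW
averages, over the `|V|−1` cuts between consecutive positions, the number of
edges whose endpoint positions straddle the cut; self edges never cross. By
default each edge counts once regardless of weight — the metric describes
the drawn layout — with a weighted variant behind a flag. Computed by a
single ±1 difference sweep in O(|E| + |V|). Cuts between different final
components are included (they contribute width 0 from the absence of
cross-component edges). ACW is invariant under globally mirroring a layout,
which the tests exercise.

## Synthetic data generator

The generator emulates the standard simulation protocol for evaluating
linearizers: a uniform-random reference fragment of 37 287 bp; per genome,
`k` variants of each type — deletions (20 bp), insertions (20 bp, random
sequence), inversions (200 bp, in-place reverse complement) and tandem
duplications (500 bp) — with `k` nominally swept over 5..11 and 10 rearranged
genomes per setting. Variant loci are drawn uniformly and independently per
genome (a shared-pool mode is available), with a ≥1 bp gap enforced between
variants of one genome so breakpoints never coincide; placement failure
after bounded retries is a clean error suggesting smaller `k`.

The graph is built directly from the known breakpoints rather than through a
multiple aligner: the reference is segmented at the union of all genomes'
breakpoints and additionally chunked to at most 32 bp per node — real graph
constructors cap node size the same way, and without the cap a variant-free
simulation would collapse to a single node instead of a chain. Deletions
skip segments, insertions visit a dedicated node (deduplicated by position
and sequence), inversions traverse their segments in reverse on the `−`
strand, and duplications revisit their block, inducing the back edge that
exercises feedback handling. The reference itself is included as a path by
default, matching how graphs are built from a genome set containing the base
fragment. Because construction is exact, correctness is testable at the
byte level: concatenating oriented node labels along each genome path must
reproduce that genome's mutated sequence exactly, and the suite checks this
at full reference size.

What the generator does not emulate: alignment noise and segment collapse
from heuristic graph construction, SNV-scale variation, breakpoint
microhomology, and overlapping/nested variants. Passing tests therefore
demonstrate correctness of the algorithm and data structures on structurally
clean graphs, not robustness to aligner artifacts in real pangenomes.

## Reference implementations and validation sizes

Two oracles back the suite. `naive_greedy` transcribes the insertion rules
with explicit orientation/position arrays and wholesale rewrites
(O(|E|·|V| log |V|)); it must match the optimized implementation exactly,
which pins down both the forest arithmetic and the rule tie-breaks.
`exhaustive_best` enumerates all orders × orientations of graphs with ≤ 8
nodes (first orientation fixed to +1 by global-reversal symmetry) and
provides the true optimum; the greedy result is never better and matches it
on chains, trees and single cycles. Validation sizes — 200 random graphs up
to 50 nodes/120 edges for equivalence, 100 up to 6 nodes against the
optimum, 10⁴ fuzzed forest operations, and simulation grid points k ∈ {0, 5,
11} at full reference length — were chosen to cover every code path many
times over while the whole suite runs in seconds.

## Known limitations

* The algorithm is a heuristic: no approximation guarantee for WRJ/WFA, and
  ACW is measured but never optimized.
* Weight ties are broken by canonical edge key; other implementations of the
  same algorithm may order ties differently and report slightly different
  metrics on tie-heavy graphs.
* GFA1 only (S/L/P); GFA2 and W lines are rejected, overlaps/CIGARs are
  ignored, and unknown record types are skipped with a warning.
* The amortized near-constant query cost is inherited from the classical
  union-find analysis; it is exercised, not formally verified, here.
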