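"""Augmented disjoint-set forest for incremental linearization.

The structure maintains, for a dynamic partition of the node set into
connected components, each node's *orientation* (+-1) and its *position*
within its component (components are always positioned on ``{1..size}``).
A plain union-find cannot afford per-node position updates at merges, so
orientation and position are stored *relative to the tree parent*:

* ``orient``         -- orientation relative to the parent (+-1),
* ``shift``          -- preliminary position relative to the parent and its
                        orientation, inherited by descendants,
* ``reorder_shift``  -- final position relative to the preliminary position,
                        NOT inherited by descendants.

The actual orientation of a node is the product of ``orient`` over the node
and its ancestors; the actual position is

    sum over proper ancestors u of  shift(u) * actual_orient(u)
    +  (shift(v) + reorder_shift(v)) * actual_orient(v).

Merging two components, or reversing one wholesale (positions p -> size+1-p
with all orientations negated), therefore costs O(1) attribute edits at a
root, and path compression folds a parent's attributes into its children in
constant time per link, preserving every node's observable values.  With
union by rank this retains the classical near-constant amortized bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping


@dataclass
class ForestStats:
    """Instrumentation: attribute writes and compression steps."""

    attribute_writes: int = 0
    compression_steps: int = 0


class LinearizationState:
    """Union-find over nodes with per-component orientations and positions."""

    def __init__(self, node_ids: Iterable[Hashable]):
        ids = list(node_ids)
        if not ids:
            raise ValueError("cannot build a state over zero nodes")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        self.ids = ids
        self.index = {v: i for i, v in enumerate(ids)}
        n = len(ids)
        self.parent = list(range(n))
        self.rank = [0] * n
        self.orient = [1] * n
        self.shift = [1] * n  # singleton position 1
        self.reorder_shift = [0] * n
        self.comp_size = {i: 1 for i in range(n)}
        self.stats = ForestStats()

    # -- queries ---------------------------------------------------------

    def find(self, v: Hashable) -> tuple[Hashable, int, int]:
        """Return (component representative, actual orientation, position).

        Performs path compression; observable orientations and positions of
        every node are unchanged by the call.
        """
        if v not in self.index:
            raise KeyError(f"unknown node {v!r}")
        root, orient, pos = self._find(self.index[v])
        return self.ids[root], orient, pos

    def _find(self, i: int) -> tuple[int, int, int]:
        parent, orient, shift = self.parent, self.orient, self.shift
        path = []
        while parent[i] != i:
            path.append(i)
            i = parent[i]
        root = i
        # Compress top-down: each node's parent is already a direct child of
        # the root when we fold the parent's orient/shift into it.
        for x in reversed(path):
            p = parent[x]
            if p != root:
                o = orient[x]
                orient[x] = o * orient[p]
                shift[x] += shift[p] * o
                parent[x] = root
                self.stats.attribute_writes += 3
            self.stats.compression_steps += 1
        # Actual values: the queried node is now the root or its direct child.
        v = path[0] if path else root
        if v == root:
            a = orient[root]
            pos = (shift[root] + self.reorder_shift[root]) * a
        else:
            a = orient[v] * orient[root]
            pos = shift[root] * orient[root] + (shift[v] + self.reorder_shift[v]) * a
        return root, a, pos

    def same_component(self, u: Hashable, v: Hashable) -> bool:
        return self.find(u)[0] == self.find(v)[0]

    def size(self, root: Hashable) -> int:
        return self.comp_size[self._require_root(root)]

    def _require_root(self, v: Hashable) -> int:
        i = self.index[v]
        if self.parent[i] != i:
            raise ValueError(f"{v!r} is not a component root")
        return i

    # -- updates ---------------------------------------------------------

    def reverse_component(self, root: Hashable) -> None:
        """Flip a whole component: positions p -> size+1-p, orientations negated.

        O(1): only the root's attributes change.
        """
        r = self._require_root(root)
        c = self.comp_size[r] + 1
        a_old = self.orient[r]
        self.orient[r] = -a_old
        self.shift[r] = (c - self.shift[r] * a_old) * self.orient[r]
        # root's reorder_shift keeps its position consistent automatically:
        # (shift' + rs) * a_new == c - (shift + rs) * a_old
        self.stats.attribute_writes += 2

    def union_merge(
        self, root_a: Hashable, root_b: Hashable, reverse_b: bool = False
    ) -> Hashable:
        """Merge two components, placing component A first.

        Nodes under ``root_a`` keep positions ``{1..n1}``; nodes under
        ``root_b`` move to ``n1 + p`` (or, with ``reverse_b``, to
        ``n1 + n2 - p + 1`` with orientations negated).  The tree parent is
        chosen by rank; O(1) attribute arithmetic at whichever root loses
        compensates, so the merged order never depends on the rank outcome.
        """
        ra, rb = self._require_root(root_a), self._require_root(root_b)
        if ra == rb:
            raise ValueError("cannot merge a component with itself")
        if reverse_b:
            self.reverse_component(root_b)
        n1 = self.comp_size[ra]

        if self.rank[ra] >= self.rank[rb]:
            # attach B's root under A's root
            a_ra, a_rb = self.orient[ra], self.orient[rb]
            self.orient[rb] = a_rb * a_ra
            self.shift[rb] += (n1 - self.shift[ra] * a_ra) * a_rb
            self.parent[rb] = ra
            new_root = ra
            if self.rank[ra] == self.rank[rb]:
                self.rank[ra] += 1
        else:
            # attach A's root under B's root: first move B by +n1 at its
            # root, then hang A so its nodes keep their values.
            a_rb = self.orient[rb]
            self.shift[rb] += n1 * a_rb
            a_ra = self.orient[ra]
            self.orient[ra] = a_ra * a_rb
            self.shift[ra] = self.shift[ra] - self.shift[rb] * a_rb * a_ra
            self.parent[ra] = rb
            new_root = rb
        self.stats.attribute_writes += 4
        total = self.comp_size.pop(ra) + self.comp_size.pop(rb)
        self.comp_size[new_root] = total
        return self.ids[new_root]

    def reposition(self, assignments: Mapping[Hashable, int]) -> None:
        """Move listed nodes to new positions via ``reorder_shift`` only.

        The targets must be a permutation of the listed nodes' current
        positions within one component; all other nodes, including
        descendants of listed nodes, keep their positions, and no
        orientation changes.
        """
        if not assignments:
            return
        found = {v: self._find(self.index[v]) for v in assignments}
        roots = {r for r, _, _ in found.values()}
        if len(roots) != 1:
            raise ValueError("reposition spans multiple components")
        current = sorted(pos for _, _, pos in found.values())
        if current != sorted(assignments.values()):
            raise ValueError(
                "assignments are not a permutation of the affected positions"
            )
        for v, target in assignments.items():
            i = self.index[v]
            _, a, pos = found[v]
            if pos != target:
                # pos changes by (rs' - rs) * a
                self.reorder_shift[i] += (target - pos) * a
                self.stats.attribute_writes += 1

    # -- bulk inspection (testing / finalization) -------------------------

    def components(self) -> dict[Hashable, list[Hashable]]:
        """Mapping root id -> member ids (no particular member order)."""
        comps: dict[Hashable, list[Hashable]] = {}
        for v in self.ids:
            comps.setdefault(self.find(v)[0], []).append(v)
        return comps

    def snapshot(self) -> dict[Hashable, tuple[Hashable, int, int]]:
        """(root, orientation, position) for every node."""
        return {v: self.find(v) for v in self.ids}
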