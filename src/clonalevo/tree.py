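"""Rooted mutation trees in parent-vector form.

A mutation tree places each mutational event (or LOH event) at a node of a
rooted tree; the root is the unmutated wild type.  A cell attached at node v
carries exactly the events on the path root -> v.  Nodes are indexed
0..n_events with 0 reserved for the root, so the tree is fully described by a
parent vector ``parent[i]`` for i = 1..n_events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

ROOT = 0


@dataclass(frozen=True)
class MutationTree:
    """Rooted tree over mutation events.

    Parameters
    ----------
    parent
        ``parent[j]`` is the parent node of event node ``j + 1`` (0 denotes the
        root), so ``len(parent)`` equals the number of events.
    labels
        Optional event labels (e.g. ``"NPM1 p.L287fs"`` or ``"RUNX1:LOH"``),
        aligned with event nodes 1..n_events.
    """

    parent: tuple[int, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.parent)
        labels = self.labels or tuple(f"m{j}" for j in range(1, n + 1))
        object.__setattr__(self, "parent", tuple(int(p) for p in self.parent))
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) != n:
            raise ValueError("labels must match the number of events")
        for j, p in enumerate(self.parent, start=1):
            if not 0 <= p <= n:
                raise ValueError(f"parent of node {j} out of range: {p}")
        # reject cycles: every node must reach the root
        for j in range(1, n + 1):
            seen = set()
            v = j
            while v != ROOT:
                if v in seen:
                    raise ValueError(f"cycle detected through node {j}")
                seen.add(v)
                v = self.parent[v - 1]

    @property
    def n_events(self) -> int:
        return len(self.parent)

    @property
    def n_nodes(self) -> int:
        return len(self.parent) + 1

    def children(self, v: int) -> list[int]:
        return [j for j in range(1, self.n_nodes) if self.parent[j - 1] == v]

    def root_path(self, v: int) -> list[int]:
        """Event nodes on the path root -> v, excluding the root, in order."""
        path = []
        while v != ROOT:
            path.append(v)
            v = self.parent[v - 1]
        return path[::-1]

    def is_ancestor(self, u: int, v: int) -> bool:
        """True iff u is an ancestor of v or u == v (root is ancestor of all)."""
        if u == ROOT:
            return True
        while v != ROOT:
            if v == u:
                return True
            v = self.parent[v - 1]
        return False

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_events) matrix; ``A[v, j]`` is True iff event
        node j+1 lies on the root path of node v (inclusive)."""
        n = self.n_events
        A = np.zeros((n + 1, n), dtype=bool)
        for v in range(1, n + 1):
            A[v, [u - 1 for u in self.root_path(v)]] = True
        return A

    def node_depths(self) -> np.ndarray:
        """Depth of every node (root = 0)."""
        d = np.zeros(self.n_nodes, dtype=int)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v - 1]] + 1
        return d

    def relabeled(self, labels: Sequence[str]) -> "MutationTree":
        return MutationTree(self.parent, tuple(labels))

    def to_newick(self) -> str:
        """Newick string with event labels on internal/leaf nodes."""

        def sub(v: int) -> str:
            kids = self.children(v)
            name = "root" if v == ROOT else self.labels[v - 1]
            if not kids:
                return name
            return "(" + ",".join(sub(c) for c in kids) + ")" + name

        return sub(ROOT) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationTree):
            return NotImplemented
        return self.parent == other.parent

    def __hash__(self) -> int:
        return hash(self.parent)


def enumerate_parent_vectors(n_events: int) -> Iterator[tuple[int, ...]]:
    """Yield every rooted mutation tree on ``n_events`` labeled events.

    There are ``(n_events + 1) ** (n_events - 1)`` such trees; feasible for
    exhaustive oracles up to ~6 events.
    """
    if n_events < 1:
        raise ValueError("need at least one event")

    def valid(parent: tuple[int, ...]) -> bool:
        for j in range(1, n_events + 1):
            v, seen = j, set()
            while v != ROOT:
                if v in seen:
                    return False
                seen.add(v)
                v = parent[v - 1]
        return True

    import itertools

    for parent in itertools.product(range(n_events + 1), repeat=n_events):
        if valid(parent):
            yield parent
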