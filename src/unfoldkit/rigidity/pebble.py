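"""(6,6) pebble game for body-and-bar frameworks.

Each body carries six pebbles (its six rigid-body degrees of freedom).
A bar between bodies u and v is independent iff seven pebbles can be
gathered on {u, v}; accepting it consumes one pebble and orients the bar.
This computes the rank of the generic body-bar rigidity matroid (Tay's
theorem), so the combinatorial result matches the rank of a generically
embedded rigidity matrix.

Rigid-cluster decomposition uses the pair test: two bodies are mutually
rigid iff one additional bar between them would be redundant (no seventh
pebble can be gathered).  Mutual rigidity is transitive and rigid
clusters are edge-connected, so a union-find over adjacent rigid pairs
recovers the full decomposition.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ..constants import DOF_PER_BODY
from .network import ConstraintNetwork


class PebbleGame:
    """Mutable pebble-game state over ``n`` bodies."""

    def __init__(self, n: int) -> None:
        if n < 1:
            raise ValueError("need at least one body")
        self.n = n
        self.pebbles = [DOF_PER_BODY] * n
        # arcs[u][v] = number of bars currently oriented u -> v
        self.arcs: list[defaultdict[int, int]] = [defaultdict(int) for _ in range(n)]
        self.n_independent = 0
        self.n_redundant = 0

    # -- pebble search ----------------------------------------------------

    def _search_and_move(self, root: int, blocked: int) -> bool:
        """DFS from ``root`` (with ``blocked`` excluded) for a free pebble;
        if found, move it to ``root`` by reversing the path arcs."""
        visited = {root, blocked}
        parent: dict[int, int] = {}
        stack = [root]
        while stack:
            x = stack.pop()
            for y, cnt in self.arcs[x].items():
                if cnt <= 0 or y in visited:
                    continue
                visited.add(y)
                parent[y] = x
                if self.pebbles[y] > 0:
                    node = y
                    while node != root:
                        p = parent[node]
                        self.arcs[p][node] -= 1
                        self.arcs[node][p] += 1
                        node = p
                    self.pebbles[y] -= 1
                    self.pebbles[root] += 1
                    return True
                stack.append(y)
        return False

    def _gather(self, u: int, v: int, target: int = DOF_PER_BODY + 1) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            if not (self._search_and_move(u, v) or self._search_and_move(v, u)):
                return False
        return True

    # -- public operations -------------------------------------------------

    def add_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns True if independent, False if redundant."""
        if u == v:
            raise ValueError("loops are not allowed in a body-bar framework")
        if self._gather(u, v):
            self.pebbles[u] -= 1
            self.arcs[u][v] += 1
            self.n_independent += 1
            return True
        self.n_redundant += 1
        return False

    def is_rigid_pair(self, u: int, v: int) -> bool:
        """True iff u and v have no relative degree of freedom left."""
        return not self._gather(u, v)

    @property
    def free_pebbles(self) -> int:
        return sum(self.pebbles)


@dataclass
class RigidDecomposition:
    """Rigid clusters, floppy modes and redundancy of one constraint network."""

    labels: np.ndarray          # cluster id per body (0-based, compressed)
    floppy_modes: int           # internal floppy modes (global motions excluded)
    n_redundant: int
    n_bodies: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.n_bodies else 0

    def clusters(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == c) for c in range(self.n_clusters)]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def giant_cluster_id(self) -> int:
        """Largest cluster; ties broken toward the lowest label."""
        return int(np.argmax(self.cluster_sizes()))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pebble_game(network: ConstraintNetwork) -> RigidDecomposition:
    """Run the (6,6) pebble game and decompose the network into rigid clusters.

    The floppy-mode count excludes the six global rigid-body motions and
    is never negative (an isolated body reports zero internal modes).
    """
    n = network.n_bodies
    game = PebbleGame(n)
    pair_seen: set[tuple[int, int]] = set()
    for edge in network.edges:
        u, v = (edge.i, edge.j) if edge.i < edge.j else (edge.j, edge.i)
        pair_seen.add((u, v))
        for _ in range(edge.bars):
            game.add_bar(u, v)

    uf = _UnionFind(n)
    for u, v in sorted(pair_seen):
        if uf.find(u) != uf.find(v) and game.is_rigid_pair(u, v):
            uf.union(u, v)

    roots = [uf.find(i) for i in range(n)]
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = order.setdefault(r, len(order))

    floppy = max(game.free_pebbles - DOF_PER_BODY, 0)
    return RigidDecomposition(labels, floppy, game.n_redundant, n)
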