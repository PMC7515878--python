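"""Aggregation graphs: monomers as vertices, non-covalent contacts as edges.

An :class:`AggregationGraph` is a simple undirected graph on vertices
``0..n-1``.  It is deliberately lightweight (adjacency sets, no attribute
machinery) because the kinetic simulator toggles single edges millions of
times; conversion helpers to :mod:`networkx` are provided for algorithms
that want the full toolkit.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

import networkx as nx

Edge = Tuple[int, int]


def _canon(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


class AggregationGraph:
    """Simple undirected graph on a fixed vertex set ``0..n-1``.

    Vertices are protein monomers; an edge is a non-covalent inter-monomer
    contact.  No self-loops, no parallel edges; ``{u, v}`` and ``{v, u}``
    are the same edge.
    """

    __slots__ = ("n", "adj", "_m")

    def __init__(self, n: int, edges: Iterable[Edge] = ()):
        if n < 1:
            raise ValueError(f"vertex count must be >= 1, got {n}")
        self.n = n
        self.adj: list[set[int]] = [set() for _ in range(n)]
        self._m = 0
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic mutation -------------------------------------------------
    def _check(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-loop on vertex {u} not allowed")
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise ValueError(f"edge ({u},{v}) outside vertex range 0..{self.n - 1}")

    def add_edge(self, u: int, v: int) -> None:
        self._check(u, v)
        if v not in self.adj[u]:
            self.adj[u].add(v)
            self.adj[v].add(u)
            self._m += 1

    def remove_edge(self, u: int, v: int) -> None:
        self._check(u, v)
        if v in self.adj[u]:
            self.adj[u].discard(v)
            self.adj[v].discard(u)
            self._m -= 1

    def toggle_edge(self, u: int, v: int) -> bool:
        """Flip edge ``{u, v}``; return True if the edge was added."""
        self._check(u, v)
        if v in self.adj[u]:
            self.remove_edge(u, v)
            return False
        self.add_edge(u, v)
        return True

    # -- queries --------------------------------------------------------
    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adj[u]

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def neighbors(self, v: int) -> set[int]:
        return self.adj[v]

    @property
    def num_edges(self) -> int:
        return self._m

    def edges(self) -> Iterator[Edge]:
        for u in range(self.n):
            for v in self.adj[u]:
                if u < v:
                    yield (u, v)

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges())

    # -- copies / conversions -------------------------------------------
    def copy(self) -> "AggregationGraph":
        g = AggregationGraph(self.n)
        g.adj = [set(s) for s in self.adj]
        g._m = self._m
        return g

    def subgraph(self, vertices: Iterable[int]) -> nx.Graph:
        """Induced subgraph on ``vertices`` as a networkx graph."""
        vs = sorted(set(vertices))
        h = nx.Graph()
        h.add_nodes_from(vs)
        vset = set(vs)
        for u in vs:
            for v in self.adj[u]:
                if v in vset and u < v:
                    h.add_edge(u, v)
        return h

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "AggregationGraph":
        """Relabel an arbitrary networkx graph onto 0..n-1 (sorted node order)."""
        nodes = sorted(g.nodes())
        idx = {v: i for i, v in enumerate(nodes)}
        out = cls(max(1, len(nodes)))
        for u, v in g.edges():
            out.add_edge(idx[u], idx[v])
        return out

    @classmethod
    def from_edge_set(cls, n: int, edges: Iterable[Edge]) -> "AggregationGraph":
        return cls(n, edges)

    def connected_components(self) -> list[set[int]]:
        """Connected components (including singletons), each a vertex set."""
        seen = [False] * self.n
        comps = []
        for s in range(self.n):
            if seen[s]:
                continue
            comp = {s}
            seen[s] = True
            stack = [s]
            while stack:
                x = stack.pop()
                for y in self.adj[x]:
                    if not seen[y]:
                        seen[y] = True
                        comp.add(y)
                        stack.append(y)
            comps.append(comp)
        return comps

    # -- dunder ----------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AggregationGraph):
            return NotImplemented
        return self.n == other.n and self.adj == other.adj

    def __hash__(self):  # mutable; identity hashing is the sane default
        return id(self)

    def __repr__(self) -> str:
        return f"AggregationGraph(n={self.n}, m={self._m})"
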