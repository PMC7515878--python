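"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates subsets/permutations directly from the motif
definitions and never calls the package's incremental machinery, so the
two routes stay independent.
"""

from __future__ import annotations

import itertools

import numpy as np

from fibrilnet import AggregationGraph


def enum_stats(g: AggregationGraph) -> np.ndarray:
    """The nine-statistic vector by exhaustive enumeration."""
    n = g.n
    edges = set(g.edges())

    def has(u, v):
        return (min(u, v), max(u, v)) in edges

    t_e = len(edges)

    # two-stars: vertex plus an unordered pair of its neighbours
    t_2s = 0
    for v in range(n):
        nb = [u for u in range(n) if has(u, v)]
        t_2s += sum(1 for _ in itertools.combinations(nb, 2))

    nsp1 = nsp2 = esp0 = esp1 = 0
    for u, v in itertools.combinations(range(n), 2):
        common = sum(1 for w in range(n) if w not in (u, v) and has(u, w) and has(v, w))
        if has(u, v):
            if common == 0:
                esp0 += 1
            elif common == 1:
                esp1 += 1
        else:
            if common == 1:
                nsp1 += 1
            elif common == 2:
                nsp2 += 1

    # cycles: per vertex subset, count distinct Hamiltonian cycles
    cyc = {5: 0, 6: 0, 7: 0}
    for k in (5, 6, 7):
        if k > n:
            continue
        for subset in itertools.combinations(range(n), k):
            first = subset[0]
            rest = subset[1:]
            seen = 0
            for perm in itertools.permutations(rest):
                cycle = (first,) + perm
                if all(
                    has(cycle[i], cycle[(i + 1) % k]) for i in range(k)
                ):
                    seen += 1
            cyc[k] += seen // 2  # each cycle traversed in two directions
    return np.array(
        [t_e, t_2s, nsp1, nsp2, esp0, esp1, cyc[5], cyc[6], cyc[7]], dtype=float
    )


def enum_change(g: AggregationGraph, u: int, v: int) -> np.ndarray:
    """Change statistics as a literal difference of enumerated stats."""
    before = enum_stats(g)
    h = g.copy()
    h.toggle_edge(u, v)
    return enum_stats(h) - before


def random_graph(n: int, p: float, rng: np.random.Generator) -> AggregationGraph:
    g = AggregationGraph(n)
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                g.add_edge(u, v)
    return g
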