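"""The nine sufficient statistics of the network Hamiltonian, and their
single-edge change statistics.

The Hamiltonian over aggregation graphs is

    H(g) = (phi_e + k_B*T) * t_e(g) + phi_2s * t_2s(g)
         + phi_NSP1 * t_NSP1(g) + phi_NSP2 * t_NSP2(g)
         + phi_ESP0 * t_ESP0(g) + phi_ESP1 * t_ESP1(g)
         + phi_C5 * t_C5(g) + phi_C6 * t_C6(g) + phi_C7 * t_C7(g)

with motif counts

* t_e     — edges,
* t_2s    — two-stars, sum over vertices of C(deg, 2),
* t_NSPk  — null shared partners: non-adjacent vertex pairs with exactly k
            common neighbours (k = 1, 2),
* t_ESPk  — edgewise shared partners: adjacent pairs with exactly k common
            neighbours (k = 0, 1),
* t_Ck    — simple cycles of length k, each cycle subgraph counted once
            (k = 5, 6, 7).

Change statistics ``t(g XOR {u,v}) - t(g)`` are computed locally (degrees,
shared-partner bookkeeping around the dyad, and a depth-limited path search
for the cycle terms), which is what makes Metropolis sampling and kinetic
rate evaluation cheap.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .graph import AggregationGraph

#: canonical statistic order used by every coefficient vector in the package
STAT_NAMES = ("e", "2s", "NSP1", "NSP2", "ESP0", "ESP1", "C5", "C6", "C7")


class SufficientStats(NamedTuple):
    """Motif counts t(g), in the canonical order of :data:`STAT_NAMES`."""

    e: int
    two_star: int
    nsp1: int
    nsp2: int
    esp0: int
    esp1: int
    c5: int
    c6: int
    c7: int

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _cycle_counts(g: AggregationGraph) -> tuple[int, int, int]:
    """Count simple cycles of length 5, 6, 7 (each cycle subgraph once).

    DFS anchored at the smallest vertex of each cycle; every cycle is
    enumerated once per direction, so totals are halved.
    """
    counts = [0, 0, 0]  # lengths 5, 6, 7
    adj = g.adj

    for a in range(g.n):
        on_path = {a}

        def dfs(v: int, depth: int) -> None:
            for w in adj[v]:
                if w == a:
                    if 4 <= depth <= 6:
                        counts[depth - 4] += 1
                elif w > a and w not in on_path and depth < 6:
                    on_path.add(w)
                    dfs(w, depth + 1)
                    on_path.discard(w)

        dfs(a, 0)
    return counts[0] // 2, counts[1] // 2, counts[2] // 2


def sufficient_stats(g: AggregationGraph) -> SufficientStats:
    """Compute the full statistic vector t(g)."""
    adj = g.adj
    t_e = g.num_edges
    t_2s = sum(d * (d - 1) // 2 for d in (len(s) for s in adj))

    nsp1 = nsp2 = esp0 = esp1 = 0
    for u in range(g.n):
        au = adj[u]
        for v in range(u + 1, g.n):
            c = len(au & adj[v])
            if v in au:
                if c == 0:
                    esp0 += 1
                elif c == 1:
                    esp1 += 1
            else:
                if c == 1:
                    nsp1 += 1
                elif c == 2:
                    nsp2 += 1

    c5, c6, c7 = _cycle_counts(g)
    return SufficientStats(t_e, t_2s, nsp1, nsp2, esp0, esp1, c5, c6, c7)


def _paths_between(g: AggregationGraph, u: int, v: int) -> tuple[int, int, int]:
    """Count simple u->v paths with 4, 5 and 6 edges (edge {u,v} absent).

    Each such path closes into one 5-, 6- or 7-cycle when {u,v} is added.
    """
    counts = [0, 0, 0]
    adj = g.adj

    # distance-to-v lower bound prunes DFS branches that cannot close a
    # cycle of length <= 7 (distances ignore the no-revisit constraint,
    # so they are a valid lower bound)
    dist = {v: 0}
    frontier = [v]
    d = 0
    while frontier and d < 5:
        d += 1
        nxt = []
        for x in frontier:
            for w in adj[x]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt

    on_path = {u}

    def dfs(x: int, depth: int) -> None:
        for w in adj[x]:
            if w == v:
                if depth >= 3:  # total edges = depth + 1 in {4,5,6}
                    counts[depth - 3] += 1
            elif (
                w not in on_path
                and depth < 5
                and depth + 1 + dist.get(w, 7) <= 6
            ):
                on_path.add(w)
                dfs(w, depth + 1)
                on_path.discard(w)

    dfs(u, 0)
    return counts[0], counts[1], counts[2]


def _add_delta(g: AggregationGraph, u: int, v: int) -> np.ndarray:
    """Statistic change from adding edge {u,v}; the edge must be absent."""
    adj = g.adj
    au, av = adj[u], adj[v]

    d = np.zeros(9)
    d[0] = 1.0
    d[1] = len(au) + len(av)

    dnsp1 = dnsp2 = desp0 = desp1 = 0
    # the dyad itself moves from the null to the edgewise category
    c_uv = len(au & av)
    if c_uv == 1:
        dnsp1 -= 1
    elif c_uv == 2:
        dnsp2 -= 1
    if c_uv == 0:
        desp0 += 1
    elif c_uv == 1:
        desp1 += 1

    # every pair {v, x} with x a neighbour of u gains u as a common partner,
    # and symmetrically {u, x} for x a neighbour of v
    for base, other in ((v, au), (u, av)):
        ab = adj[base]
        for x in other:
            if x == base:
                continue
            c = len(ab & adj[x])
            if x in ab:  # edgewise pair: category c -> c+1
                if c == 0:
                    desp0 -= 1
                    desp1 += 1
                elif c == 1:
                    desp1 -= 1
            else:  # null pair: category c -> c+1
                if c == 0:
                    dnsp1 += 1
                elif c == 1:
                    dnsp1 -= 1
                    dnsp2 += 1
                elif c == 2:
                    dnsp2 -= 1

    d[2], d[3], d[4], d[5] = dnsp1, dnsp2, desp0, desp1
    d[6], d[7], d[8] = _paths_between(g, u, v)
    return d


def change_stats(g: AggregationGraph, u: int, v: int) -> np.ndarray:
    """Signed statistic delta for toggling edge {u, v}.

    Returns ``t(g XOR {u,v}) - t(g)`` as a length-9 float array in the
    canonical statistic order.  Raises ``ValueError`` on ``u == v``.
    """
    if u == v:
        raise ValueError(f"dyad requires two distinct vertices, got ({u},{v})")
    if g.has_edge(u, v):
        g.remove_edge(u, v)
        try:
            delta = -_add_delta(g, u, v)
        finally:
            g.add_edge(u, v)
        return delta
    return _add_delta(g, u, v)


def hamiltonian(g: AggregationGraph, params) -> float:
    """Energy H(g) of the aggregation graph under ``params``.

    The edge statistic carries coefficient ``phi_e + k_B*T``; all other
    statistics carry their bare ``phi``.
    """
    return float(np.dot(params.coeffs, sufficient_stats(g).as_array()))


def energy_delta(g: AggregationGraph, u: int, v: int, params) -> float:
    """H(g XOR {u,v}) - H(g), via change statistics."""
    return float(np.dot(params.coeffs, change_stats(g, u, v)))
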