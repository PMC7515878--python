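"""Vertex roles and the bonding-motif census of fibril defects.

Monomers are assigned one of four roles relative to the induced fibrillar
components:

* ``end``    — fibrillar monomer in the first or last subunit of its segment;
* ``center`` — any other fibrillar monomer (fibril interior);
* ``defect`` — non-fibrillar monomer in an aggregate that contains
  fibrillar monomers;
* ``free``   — monomer in an aggregate with no fibrillar content.

Every edge that is not internal to a single fibrillar component is
classified by its endpoint roles (end–end, end–center, defect–center, ...);
this closed role-pair taxonomy necessarily covers every observable bonding
motif.  A *defect breakage* event is an edge deletion incident to at least
one defect that splits an aggregate into two.
"""

from __future__ import annotations

from typing import Union

import pandas as pd

from .graph import AggregationGraph
from .kinetics import Trajectory
from .topology import (
    FibrilTemplate,
    FibrillarComponentSet,
    get_template,
    induced_fibrillar_components,
)

__all__ = [
    "ROLES",
    "CENSUS_CATEGORIES",
    "vertex_roles",
    "motif_census",
    "detect_breakage_events",
]

ROLES = ("end", "center", "defect", "free")

# canonical order inside a category name: defect first, then end, center, free
_ROLE_RANK = {"defect": 0, "end": 1, "center": 2, "free": 3}

#: every role pair that an edge can realize (same-component fibril-internal
#: edges are excluded from the census; free monomers cannot bond fibrillar
#: content without ceasing to be free, so mixed free pairs never occur)
CENSUS_CATEGORIES = (
    "end_end",
    "end_center",
    "center_center",
    "defect_end",
    "defect_center",
    "defect_defect",
    "free_free",
)


def vertex_roles(
    g: AggregationGraph,
    template: Union[str, FibrilTemplate],
    components: FibrillarComponentSet | None = None,
    mode: str = "partial",
) -> dict[int, str]:
    """Role per vertex; pass ``components`` to reuse a prior extraction."""
    t = get_template(template)
    if components is None:
        components = induced_fibrillar_components(g, t, mode=mode)
    roles = {}
    fibrillar = components.fibrillar_vertices
    for comp in components.components:
        terminals = comp.terminal_vertices
        for v in comp.vertices:
            roles[v] = "end" if v in terminals else "center"
    for aggregate in g.connected_components():
        has_fibril = any(v in fibrillar for v in aggregate)
        for v in aggregate:
            if v not in roles:
                roles[v] = "defect" if has_fibril else "free"
    return roles


def _pair_key(r1: str, r2: str) -> str:
    a, b = sorted((r1, r2), key=_ROLE_RANK.__getitem__)
    return f"{a}_{b}"


def motif_census(
    g: AggregationGraph,
    template: Union[str, FibrilTemplate],
    components: FibrillarComponentSet | None = None,
    mode: str = "partial",
) -> dict[str, int]:
    """Counts of non-fibril-internal edges by endpoint role pair.

    Edges internal to a single fibrillar component are the fibril itself
    and are excluded; every other edge lands in exactly one category, so
    the category counts partition those edges.
    """
    t = get_template(template)
    if components is None:
        components = induced_fibrillar_components(g, t, mode=mode)
    roles = vertex_roles(g, t, components=components)
    comp_of = {}
    for i, comp in enumerate(components.components):
        for v in comp.vertices:
            comp_of[v] = i
    census = {k: 0 for k in CENSUS_CATEGORIES}
    for u, v in g.edges():
        cu, cv = comp_of.get(u), comp_of.get(v)
        if cu is not None and cu == cv:
            continue  # fibril-internal
        census[_pair_key(roles[u], roles[v])] += 1
    return census


def detect_breakage_events(
    traj: Trajectory,
    template: Union[str, FibrilTemplate],
    bin_events: int = 1000,
    mode: str = "partial",
) -> pd.DataFrame:
    """Defect-breakage events per event-count bin.

    A defect breakage is an edge deletion incident to at least one
    defect-role vertex (roles evaluated in the pre-deletion state) that
    disconnects the aggregate it belonged to.  Returns one row per bin:
    ``bin_start_event``, ``bin_end_event``, ``t_start``, ``t_end``,
    ``defect_breakage``.
    """
    if bin_events < 1:
        raise ValueError("bin_events must be >= 1")
    t = get_template(template)
    g = AggregationGraph(traj.n)
    n_events = len(traj.events)
    n_bins = max(1, -(-n_events // bin_events))
    counts = [0] * n_bins
    t_prev = 0.0
    bin_times = []
    for ev in traj.events:
        if ev.kind == "del":
            roles = vertex_roles(g, t, mode=mode)
            if roles[ev.u] == "defect" or roles[ev.v] == "defect":
                g.remove_edge(ev.u, ev.v)
                disconnected = not _connected(g, ev.u, ev.v)
                g.add_edge(ev.u, ev.v)
                if disconnected:
                    counts[ev.index // bin_events] += 1
        g.toggle_edge(ev.u, ev.v)
    for i in range(n_bins):
        lo = i * bin_events
        hi = min((i + 1) * bin_events, n_events)
        t_start = traj.events[lo].time if lo < n_events else t_prev
        t_end = traj.events[hi - 1].time if hi > 0 else t_start
        bin_times.append((lo, hi, t_start, t_end))
    if n_events == 0:
        return pd.DataFrame(
            columns=[
                "bin_start_event",
                "bin_end_event",
                "t_start",
                "t_end",
                "defect_breakage",
            ]
        )
    return pd.DataFrame(
        [
            (lo, hi, ts, te, counts[i])
            for i, (lo, hi, ts, te) in enumerate(bin_times)
        ],
        columns=[
            "bin_start_event",
            "bin_end_event",
            "t_start",
            "t_end",
            "defect_breakage",
        ],
    )


def _connected(g: AggregationGraph, u: int, v: int) -> bool:
    if u == v:
        return True
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in g.adj[x]:
            if y == v:
                return True
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return False
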