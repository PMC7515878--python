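"""The five amyloid fibril topology classes and induced fibrillar components.

Every fibril class observed in the PDB is a periodic graph built from a
minimal repeating subunit: the 1-ribbon (a path), the 2-ribbon (a ladder),
the 1,2 2-ribbon (a ladder whose rails also bond second neighbours), the
double 1,2 2-ribbon (two laterally bonded 1,2 2-ribbons) and the 3-prism
(stacked bonded triangles).  Templates are declarative data — a subunit
edge pattern plus inter-subunit edge patterns at offsets 1 and 2 — so the
patterns can be adjusted without code changes.

A monomer is *locally fibrillar* when its bonding neighbourhood realizes
the neighbourhood of some position (interior or terminal) of the ideal
fibril.  Two semantics are offered:

* ``mode="partial"`` (default): some subset of the monomer's bonds forms a
  template position's closed neighbourhood as an induced subgraph; bonds
  beyond that subset (e.g. to defects) are tolerated.  This is what lets a
  fibril-center monomer keep its fibrillar status when a defect attaches
  to it.
* ``mode="exact"``: the entire closed 1-neighbourhood must match a template
  position — any extra bond disqualifies the monomer.

An *induced fibrillar component* is a maximal connected set of locally
fibrillar monomers whose induced subgraph is a contiguous run of template
subunits (at least two — the nucleation threshold; four monomers for the
1-ribbon, where a two-subunit cutoff would declare every bonded dimer
fibrillar).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Union

import networkx as nx
from networkx.algorithms import isomorphism as iso

from .graph import AggregationGraph

__all__ = [
    "FibrilTemplate",
    "TEMPLATES",
    "get_template",
    "ideal_fibril",
    "nucleation_threshold",
    "is_locally_fibrillar",
    "FibrillarComponent",
    "FibrillarComponentSet",
    "induced_fibrillar_components",
    "classify_topology",
    "AmbiguousTopologyError",
    "NON_FIBRILLAR",
]

NON_FIBRILLAR = "non-fibrillar"


@dataclass(frozen=True)
class FibrilTemplate:
    """Declarative periodic fibril pattern.

    ``intra_edges`` are vertex-index pairs within one subunit;
    ``inter_edges`` are ``(i, j, offset)`` triples bonding vertex ``i`` of
    subunit ``k`` to vertex ``j`` of subunit ``k + offset``.
    """

    class_id: str
    subunit_size: int
    intra_edges: tuple[tuple[int, int], ...] = ()
    inter_edges: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self):
        if self.subunit_size < 1:
            raise ValueError("subunit_size must be >= 1")
        for i, j in self.intra_edges:
            if not (0 <= i < self.subunit_size and 0 <= j < self.subunit_size):
                raise ValueError(f"intra edge ({i},{j}) outside subunit")
        for i, j, off in self.inter_edges:
            if off < 1:
                raise ValueError("inter-edge offset must be >= 1")

    @property
    def max_offset(self) -> int:
        return max((off for _, _, off in self.inter_edges), default=1)


#: shipped default templates for the five PDB fibril topology classes
TEMPLATES: dict[str, FibrilTemplate] = {
    "1-ribbon": FibrilTemplate(
        "1-ribbon", 1, intra_edges=(), inter_edges=((0, 0, 1),)
    ),
    "2-ribbon": FibrilTemplate(
        "2-ribbon",
        2,
        intra_edges=((0, 1),),
        inter_edges=((0, 0, 1), (1, 1, 1)),
    ),
    "1,2 2-ribbon": FibrilTemplate(
        "1,2 2-ribbon",
        2,
        intra_edges=((0, 1),),
        inter_edges=((0, 0, 1), (1, 1, 1), (0, 0, 2), (1, 1, 2)),
    ),
    "double 1,2 2-ribbon": FibrilTemplate(
        "double 1,2 2-ribbon",
        4,
        intra_edges=((0, 1), (2, 3), (1, 2)),
        inter_edges=(
            (0, 0, 1),
            (1, 1, 1),
            (2, 2, 1),
            (3, 3, 1),
            (0, 0, 2),
            (1, 1, 2),
            (2, 2, 2),
            (3, 3, 2),
        ),
    ),
    "3-prism": FibrilTemplate(
        "3-prism",
        3,
        intra_edges=((0, 1), (1, 2), (0, 2)),
        inter_edges=((0, 0, 1), (1, 1, 1), (2, 2, 1)),
    ),
}

_ALIASES = {
    "1-ribbon": "1-ribbon",
    "1ribbon": "1-ribbon",
    "2-ribbon": "2-ribbon",
    "2ribbon": "2-ribbon",
    "1,2 2-ribbon": "1,2 2-ribbon",
    "1,2-2-ribbon": "1,2 2-ribbon",
    "12-2-ribbon": "1,2 2-ribbon",
    "double 1,2 2-ribbon": "double 1,2 2-ribbon",
    "double-1,2-2-ribbon": "double 1,2 2-ribbon",
    "double-12-2-ribbon": "double 1,2 2-ribbon",
    "3-prism": "3-prism",
    "3prism": "3-prism",
}


def get_template(t: Union[str, FibrilTemplate]) -> FibrilTemplate:
    """Resolve a template object or class name (aliases accepted)."""
    if isinstance(t, FibrilTemplate):
        return t
    key = _ALIASES.get(t.strip().lower().replace("_", "-"))
    if key is None:
        raise KeyError(
            f"unknown fibril class {t!r}; known: {sorted(TEMPLATES)}"
        )
    return TEMPLATES[key]


def load_template_file(path) -> FibrilTemplate:
    """Load a declarative template spec (YAML or JSON).

    Keys: ``class_id``, ``subunit_size``, ``intra_edges`` (pairs),
    ``inter_edges`` (``[i, j, offset]`` triples).
    """
    import json
    from pathlib import Path

    import yaml

    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return FibrilTemplate(
        class_id=str(raw["class_id"]),
        subunit_size=int(raw["subunit_size"]),
        intra_edges=tuple(tuple(e) for e in raw.get("intra_edges", ())),
        inter_edges=tuple(tuple(e) for e in raw.get("inter_edges", ())),
    )


def save_template_file(t: FibrilTemplate, path) -> None:
    import json
    from pathlib import Path

    import yaml

    data = {
        "class_id": t.class_id,
        "subunit_size": t.subunit_size,
        "intra_edges": [list(e) for e in t.intra_edges],
        "inter_edges": [list(e) for e in t.inter_edges],
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def ideal_fibril(template: Union[str, FibrilTemplate], length: int) -> AggregationGraph:
    """The length-``length`` (in subunits) ideal fibril graph.

    Vertices are labeled subunit-major: vertex ``k * s + i`` is position
    ``i`` of subunit ``k``.
    """
    t = get_template(template)
    if length < 1:
        raise ValueError(f"fibril length must be >= 1 subunit, got {length}")
    s = t.subunit_size
    g = AggregationGraph(s * length)
    for k in range(length):
        for i, j in t.intra_edges:
            g.add_edge(k * s + i, k * s + j)
        for i, j, off in t.inter_edges:
            if k + off < length:
                g.add_edge(k * s + i, (k + off) * s + j)
    return g


def nucleation_threshold(template: Union[str, FibrilTemplate]) -> int:
    """Minimum monomer count for an induced fibrillar component.

    Two full minimal repeating subunits, except single-monomer subunits
    (the 1-ribbon), where the threshold is four so that a lone bonded
    dimer does not count as fibrillar.
    """
    t = get_template(template)
    if t.subunit_size == 1:
        return 4
    return 2 * t.subunit_size


# ---------------------------------------------------------------------------
# local fibrillarity
# ---------------------------------------------------------------------------


def _rooted_ego(G: nx.Graph, v) -> nx.Graph:
    ego = nx.ego_graph(G, v, radius=1)
    ego = ego.copy()
    for node in ego.nodes:
        ego.nodes[node]["root"] = node == v
    return ego


def _root_match(a: dict, b: dict) -> bool:
    return bool(a.get("root")) == bool(b.get("root"))


@lru_cache(maxsize=None)
def _position_archetypes(t: FibrilTemplate) -> tuple[nx.Graph, ...]:
    """Distinct rooted closed-neighbourhood graphs of ideal-fibril positions.

    Built from a reference fibril long enough that middle positions carry
    the full periodic context; terminal positions contribute the truncated
    neighbourhoods seen at fibril ends.
    """
    length = 2 * t.max_offset + 3
    ref = ideal_fibril(t, length).to_networkx()
    archetypes: list[nx.Graph] = []
    for v in ref.nodes:
        ego = _rooted_ego(ref, v)
        if not any(
            nx.is_isomorphic(ego, a, node_match=_root_match) for a in archetypes
        ):
            archetypes.append(ego)
    return tuple(archetypes)


def is_locally_fibrillar(
    g: AggregationGraph,
    v: int,
    template: Union[str, FibrilTemplate],
    mode: str = "partial",
) -> bool:
    """Does monomer ``v``'s bonding neighbourhood realize a template position?

    ``mode="partial"`` tolerates extra bonds beyond the template pattern;
    ``mode="exact"`` requires the whole closed 1-neighbourhood to match.
    Isolated monomers are never fibrillar.
    """
    t = get_template(template)
    if not 0 <= v < g.n:
        raise ValueError(f"vertex {v} not in graph")
    if g.degree(v) == 0:
        return False
    ego = _rooted_ego(g.subgraph(g.adj[v] | {v}), v)
    for arch in _position_archetypes(t):
        if mode == "exact":
            if nx.is_isomorphic(ego, arch, node_match=_root_match):
                return True
        elif mode == "partial":
            if len(ego) >= len(arch) and iso.GraphMatcher(
                ego, arch, node_match=_root_match
            ).subgraph_is_isomorphic():
                return True
        else:
            raise ValueError(f"unknown mode {mode!r}; use 'partial' or 'exact'")
    return False


# ---------------------------------------------------------------------------
# induced fibrillar components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibrillarComponent:
    """One induced fibrillar component: vertices plus their subunit indices."""

    class_id: str
    vertices: frozenset[int]
    subunit_index: tuple[tuple[int, int], ...]  # (vertex, subunit) pairs

    @property
    def size(self) -> int:
        return len(self.vertices)

    @property
    def subunits(self) -> dict[int, int]:
        return dict(self.subunit_index)

    @property
    def terminal_vertices(self) -> frozenset[int]:
        """Vertices in the first or last subunit of the segment."""
        sub = self.subunits
        lo = min(sub.values())
        hi = max(sub.values())
        return frozenset(v for v, k in sub.items() if k in (lo, hi))


@dataclass
class FibrillarComponentSet:
    """Disjoint induced fibrillar components of a graph under one template."""

    template: FibrilTemplate
    components: list[FibrillarComponent]

    @property
    def sizes(self) -> list[int]:
        return sorted((c.size for c in self.components), reverse=True)

    @property
    def count(self) -> int:
        return len(self.components)

    @property
    def max_size(self) -> int:
        return max((c.size for c in self.components), default=0)

    @property
    def fibrillar_vertices(self) -> frozenset[int]:
        out: set[int] = set()
        for c in self.components:
            out |= c.vertices
        return frozenset(out)

    def component_of(self, v: int) -> FibrillarComponent | None:
        for c in self.components:
            if v in c.vertices:
                return c
        return None


@lru_cache(maxsize=None)
def _segment_graph(t: FibrilTemplate, length: int) -> nx.Graph:
    return ideal_fibril(t, length).to_networkx()


def _match_segment(
    g: AggregationGraph, vertices: frozenset[int], t: FibrilTemplate
) -> dict[int, int] | None:
    """If the induced subgraph on ``vertices`` is a whole-subunit segment,
    return a vertex -> subunit-index map, else None."""
    s = t.subunit_size
    if len(vertices) % s != 0:
        return None
    length = len(vertices) // s
    if length < 1:
        return None
    sub = g.subgraph(vertices)
    ref = _segment_graph(t, length)
    if sub.number_of_edges() != ref.number_of_edges():
        return None
    gm = iso.GraphMatcher(sub, ref)
    if not gm.is_isomorphic():
        return None
    return {v: ref_node // s for v, ref_node in gm.mapping.items()}


#: exploration budget per seed when searching extension choices; branch
#: points beyond this fall back to the first valid extension
_EXTENSION_BUDGET = 800


def _mine_segments(
    g: AggregationGraph,
    component: set[int],
    t: FibrilTemplate,
    used: set[int],
) -> list[list[tuple[int, ...]]]:
    """Template-guided extraction of disjoint whole-subunit segments.

    Seeds are induced embeddings of the two-subunit nucleus among unused
    vertices.  Each seed is extended subunit-by-subunit in both directions,
    exploring branch choices up to a fixed budget; each round keeps the
    longest extension over all seeds (ties broken by sorted vertex labels),
    so the decomposition does not depend on vertex labeling except at
    genuine structural ties.
    """
    s = t.subunit_size
    nucleus = _segment_graph(t, 2)
    segments: list[list[tuple[int, ...]]] = []

    def induced_ok(new: tuple[int, ...], segs: tuple[tuple[int, ...], ...], at_tail: bool) -> bool:
        """Induced edges between `new` and the segment (and within `new`)
        must exactly match the template pattern."""
        seg_vertices = {v for tup in segs for v in tup}
        required: set[frozenset[int]] = set()
        for i, j in t.intra_edges:
            required.add(frozenset((new[i], new[j])))
        m = len(segs)  # new subunit sits at index m (tail) or -1 (head)
        for i, j, off in t.inter_edges:
            if at_tail:
                if m - off >= 0:
                    required.add(frozenset((segs[m - off][i], new[j])))
            else:
                if off - 1 < m:
                    required.add(frozenset((new[i], segs[off - 1][j])))
        for e in required:
            a, b = tuple(e)
            if not g.has_edge(a, b):
                return False
        new_set = set(new)
        for a in new:
            for b in g.adj[a]:
                if b in new_set and a < b and frozenset((a, b)) not in required:
                    return False
                if b in seg_vertices and frozenset((a, b)) not in required:
                    return False
        return True

    max_off = t.max_offset

    def candidate_subunits(segs: tuple[tuple[int, ...], ...], at_tail: bool) -> list[tuple[int, ...]]:
        """All valid one-subunit extensions at the given side."""
        anchors = segs[-max_off:] if at_tail else segs[:max_off]
        taken = {v for tup in segs for v in tup}
        pool = sorted(
            {
                w
                for tup in anchors
                for a in tup
                for w in g.adj[a]
                if w in component and w not in used and w not in taken
            }
        )
        if len(pool) < s:
            return []
        out: list[tuple[int, ...]] = []
        assignment: list[int] = []

        def backtrack(pos: int) -> None:
            if pos == s:
                new = tuple(assignment)
                if induced_ok(new, segs, at_tail):
                    out.append(new)
                return
            for w in pool:
                if w in assignment:
                    continue
                assignment.append(w)
                backtrack(pos + 1)
                assignment.pop()

        backtrack(0)
        return out

    def best_extension(seed: tuple[tuple[int, ...], ...]):
        """Longest maximal extension of a seed (bounded branch search).

        The tail is always grown before the head, so a branch arises only
        at genuine structural choices and straight runs cost O(length).
        """
        budget = _EXTENSION_BUDGET
        best: tuple[tuple, tuple] | None = None

        stack = [seed]
        while stack and budget > 0:
            segs = stack.pop()
            while budget > 0:
                budget -= 1
                cands = candidate_subunits(segs, True)
                at_tail = True
                if not cands:
                    cands = candidate_subunits(segs, False)
                    at_tail = False
                if not cands:
                    break  # maximal
                if at_tail:
                    for new in cands[1:]:
                        stack.append(segs + (new,))
                    segs = segs + (cands[0],)
                else:
                    for new in cands[1:]:
                        stack.append((new,) + segs)
                    segs = (cands[0],) + segs
            key = (
                -len(segs),
                tuple(sorted(v for tup in segs for v in tup)),
            )
            if best is None or key < best[0]:
                best = (key, segs)
        return best

    while True:
        avail = sorted(v for v in component if v not in used)
        sub = g.subgraph(avail)
        seeds: list[tuple[tuple[int, ...], ...]] = []
        seen_seeds: set[frozenset[int]] = set()
        for mapping in iso.GraphMatcher(sub, nucleus).subgraph_isomorphisms_iter():
            inv = {ref: v for v, ref in mapping.items()}
            seed = tuple(
                tuple(inv[k * s + i] for i in range(s)) for k in range(2)
            )
            key = frozenset(inv.values())
            if key not in seen_seeds:
                seen_seeds.add(key)
                seeds.append(seed)
        if not seeds:
            break
        overall = None
        best_vertices: frozenset[int] = frozenset()
        n_avail = len(avail)
        for seed in seeds:
            if all(v in best_vertices for tup in seed for v in tup):
                continue  # the best segment so far already covers this seed
            cand = best_extension(seed)
            if overall is None or cand < overall:
                overall = cand
                best_vertices = frozenset(overall[0][1])
            if -overall[0][0] * s == n_avail:
                break  # a segment already spans every available vertex
        segs = overall[1]
        segments.append(list(segs))
        used.update(v for tup in segs for v in tup)
    return segments


def induced_fibrillar_components(
    g: AggregationGraph,
    template: Union[str, FibrilTemplate],
    mode: str = "partial",
) -> FibrillarComponentSet:
    """Extract the disjoint induced fibrillar components of ``g``.

    Locally fibrillar monomers are grouped into connected sets; each set is
    accepted outright when its induced subgraph is a whole-subunit segment
    of the ideal fibril, and otherwise mined greedily for disjoint maximal
    segments.  Components below the nucleation threshold are discarded.
    """
    t = get_template(template)
    thr = nucleation_threshold(t)
    fib = [v for v in range(g.n) if is_locally_fibrillar(g, v, t, mode=mode)]
    sub = g.subgraph(fib)

    components: list[FibrillarComponent] = []
    for comp in sorted(nx.connected_components(sub), key=min):
        comp = set(comp)
        if len(comp) < thr:
            continue
        mapping = _match_segment(g, frozenset(comp), t)
        if mapping is not None:
            components.append(
                FibrillarComponent(
                    t.class_id,
                    frozenset(comp),
                    tuple(sorted(mapping.items())),
                )
            )
            continue
        used: set[int] = set()
        for segs in _mine_segments(g, comp, t, used):
            verts = {v for tup in segs for v in tup}
            if len(verts) < thr:
                continue
            sub_idx = {
                v: k for k, tup in enumerate(segs) for v in tup
            }
            components.append(
                FibrillarComponent(
                    t.class_id, frozenset(verts), tuple(sorted(sub_idx.items()))
                )
            )
    components.sort(key=lambda c: min(c.vertices))
    return FibrillarComponentSet(t, components)


# ---------------------------------------------------------------------------
# whole-graph classification
# ---------------------------------------------------------------------------


class AmbiguousTopologyError(ValueError):
    """A graph matched more than one fibril class; never silently resolved."""

    def __init__(self, matches: list[str]):
        self.matches = matches
        super().__init__(f"graph matches multiple fibril classes: {matches}")


def classify_topology(
    g: AggregationGraph,
    templates: Iterable[Union[str, FibrilTemplate]] | None = None,
) -> str:
    """Classify a graph against the five fibril classes.

    Matches by isomorphism to an ideal fibril of the appropriate length;
    when the whole graph does not match, its largest connected component is
    tried.  Returns the class label, ``"non-fibrillar"`` when nothing
    matches, and raises :class:`AmbiguousTopologyError` on ties.
    """
    ts = [get_template(t) for t in (templates or TEMPLATES.values())]

    def matches_for(vertices: frozenset[int]) -> list[str]:
        found = []
        for t in ts:
            if _match_segment(g, vertices, t) is not None:
                found.append(t.class_id)
        return found

    if g.num_edges == 0:
        return NON_FIBRILLAR
    whole = frozenset(range(g.n))
    found = matches_for(whole)
    if not found:
        largest = max(g.connected_components(), key=len)
        if len(largest) < g.n and len(largest) > 1:
            found = matches_for(frozenset(largest))
    if not found:
        return NON_FIBRILLAR
    if len(found) > 1:
        raise AmbiguousTopologyError(found)
    return found[0]
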