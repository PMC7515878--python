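"""Fibril templates, local fibrillarity, and induced fibrillar components."""

import numpy as np
import pytest

from fibrilnet import (
    AggregationGraph,
    AmbiguousTopologyError,
    TEMPLATES,
    classify_topology,
    get_template,
    ideal_fibril,
    induced_fibrillar_components,
    is_locally_fibrillar,
    make_fixture,
    nucleation_threshold,
)
from fibrilnet.topology import load_template_file, save_template_file


class TestIdealFibrils:
    def test_one_ribbon_is_a_path(self):
        g = ideal_fibril("1-ribbon", 5)
        assert (g.n, g.num_edges) == (5, 4)
        degs = sorted(g.degree(v) for v in range(5))
        assert degs == [1, 1, 2, 2, 2]

    def test_three_prism_length_two_is_the_prism_graph(self):
        import networkx as nx

        g = ideal_fibril("3-prism", 2)
        assert (g.n, g.num_edges) == (6, 9)
        prism = nx.circular_ladder_graph(3)  # the triangular prism
        assert nx.is_isomorphic(g.to_networkx(), prism)

    @pytest.mark.parametrize("length", [2, 5, 9])
    def test_two_ribbon_edge_count_formula(self, length):
        """2L vertices, L rungs plus 2(L-1) rails."""
        g = ideal_fibril("2-ribbon", length)
        assert g.n == 2 * length
        assert g.num_edges == length + 2 * (length - 1)

    def test_templates_are_periodic(self):
        """Consecutive-subunit blocks are isomorphic along the fibril."""
        import networkx as nx

        for name, t in TEMPLATES.items():
            g = ideal_fibril(t, 8)
            s = t.subunit_size
            blocks = []
            for k in (2, 3, 4):  # interior pairs only
                vs = list(range(k * s, (k + 2) * s))
                blocks.append(g.subgraph(vs))
            assert nx.is_isomorphic(blocks[0], blocks[1])
            assert nx.is_isomorphic(blocks[1], blocks[2])

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            ideal_fibril("1-ribbon", 0)


class TestThresholds:
    def test_two_subunit_rule(self):
        assert nucleation_threshold("3-prism") == 6
        assert nucleation_threshold("2-ribbon") == 4
        assert nucleation_threshold("1,2 2-ribbon") == 4
        assert nucleation_threshold("double 1,2 2-ribbon") == 8

    def test_one_ribbon_exception_is_four(self):
        """A two-subunit cutoff would make every bonded dimer fibrillar."""
        assert nucleation_threshold("1-ribbon") == 4


class TestLocalFibrillarity:
    def test_interior_vertex_of_ideal_ribbon(self):
        g = ideal_fibril("1-ribbon", 6)
        assert is_locally_fibrillar(g, 3, "1-ribbon")
        assert is_locally_fibrillar(g, 3, "1-ribbon", mode="exact")

    def test_isolated_vertex_never_fibrillar(self):
        g = AggregationGraph(3, [(1, 2)])
        assert not is_locally_fibrillar(g, 0, "1-ribbon")
        assert not is_locally_fibrillar(g, 0, "1-ribbon", mode="exact")

    def test_high_degree_hub_fails_exact_matching(self):
        """Max degree in a path is 2; a degree-5 hub cannot match exactly."""
        g = AggregationGraph(8, [(0, i) for i in range(1, 6)])
        assert not is_locally_fibrillar(g, 0, "1-ribbon", mode="exact")

    def test_partial_mode_tolerates_an_extra_bond(self):
        """A fibril-center monomer keeps fibrillar status when a defect
        attaches to it (its chain bonds still realize the template)."""
        g = make_fixture("fibril_with_defect", template="1-ribbon", length=10)
        center = 5
        assert is_locally_fibrillar(g, center, "1-ribbon", mode="partial")
        assert not is_locally_fibrillar(g, center, "1-ribbon", mode="exact")


class TestInducedComponents:
    def test_ideal_ribbon_is_one_component(self):
        g = ideal_fibril("1-ribbon", 10)
        cs = induced_fibrillar_components(g, "1-ribbon")
        assert cs.count == 1
        assert cs.sizes == [10]

    def test_end_to_end_joining_merges_components(self):
        """Joining two equal fibrils halves the count and doubles the size."""
        g = make_fixture("two_fibrils_joined", template="1-ribbon", length=10)
        before = induced_fibrillar_components(
            ideal_fibril("1-ribbon", 10), "1-ribbon"
        )
        after = induced_fibrillar_components(g, "1-ribbon")
        assert (before.count, after.count) == (1, 1)
        # the two disjoint fibrils had 2 components in the unjoined graph
        unjoined = AggregationGraph(20, list(ideal_fibril("1-ribbon", 10).edges())
                                    + [(u + 10, v + 10) for u, v in ideal_fibril("1-ribbon", 10).edges()])
        assert induced_fibrillar_components(unjoined, "1-ribbon").count == 2
        assert after.max_size == 2 * before.max_size == 20

    def test_short_path_below_threshold_is_not_a_component(self):
        g = AggregationGraph(3, [(0, 1), (1, 2)])
        assert induced_fibrillar_components(g, "1-ribbon").count == 0

    @pytest.mark.parametrize("name", sorted(TEMPLATES))
    def test_ideal_fibrils_are_fully_fibrillar(self, name):
        t = get_template(name)
        length = max(2, -(-nucleation_threshold(t) // t.subunit_size))
        g = ideal_fibril(t, length + 3)
        cs = induced_fibrillar_components(g, t)
        assert cs.count == 1
        assert cs.max_size == g.n

    def test_components_invariant_under_relabeling(self, rng):
        g = make_fixture("fibril_with_defect", template="2-ribbon", length=6)
        perm = rng.permutation(g.n)
        h = AggregationGraph(
            g.n, [(int(perm[u]), int(perm[v])) for u, v in g.edges()]
        )
        a = induced_fibrillar_components(g, "2-ribbon")
        b = induced_fibrillar_components(h, "2-ribbon")
        assert sorted(c.size for c in a.components) == sorted(
            c.size for c in b.components
        )

    def test_deleting_an_edge_never_grows_the_largest_component(self):
        g = make_fixture("two_fibrils_joined", template="1-ribbon", length=10)
        base = induced_fibrillar_components(g, "1-ribbon").max_size
        for u, v in list(g.edges()):
            h = g.copy()
            h.remove_edge(u, v)
            assert (
                induced_fibrillar_components(h, "1-ribbon").max_size <= base
            )

    def test_components_are_segments_of_the_ideal_fibril(self):
        """Each extracted component induces a contiguous subunit run."""
        import networkx as nx

        g = make_fixture("fibril_with_defect", template="3-prism", length=4)
        cs = induced_fibrillar_components(g, "3-prism")
        for comp in cs.components:
            seg = ideal_fibril("3-prism", comp.size // 3)
            assert nx.is_isomorphic(g.subgraph(comp.vertices), seg.to_networkx())


class TestClassification:
    def test_all_five_classes_recognized_distinctly(self):
        labels = {classify_topology(ideal_fibril(t, 12)) for t in TEMPLATES}
        assert labels == set(TEMPLATES)

    def test_empty_graph_is_non_fibrillar(self):
        assert classify_topology(AggregationGraph(6)) == "non-fibrillar"

    def test_dense_graph_is_non_fibrillar(self):
        g = AggregationGraph(5, [(u, v) for u in range(5) for v in range(u + 1, 5)])
        assert classify_topology(g) == "non-fibrillar"

    def test_tie_is_reported_not_swallowed(self):
        """A single edge is a valid length-2 1-ribbon and a length-1
        2-ribbon subunit; the tie must surface."""
        g = AggregationGraph(2, [(0, 1)])
        with pytest.raises(AmbiguousTopologyError) as err:
            classify_topology(g)
        assert set(err.value.matches) >= {"1-ribbon", "2-ribbon"}


def test_template_file_round_trip(tmp_path):
    t = get_template("double 1,2 2-ribbon")
    path = tmp_path / "t.yaml"
    save_template_file(t, path)
    assert load_template_file(path) == t
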