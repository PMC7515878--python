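"""Per-frame aggregation metrics and epoch segmentation."""

import numpy as np
import pandas as pd
import pytest

from fibrilnet import (
    AggregationGraph,
    EpochUndetectableError,
    graph_metrics,
    ideal_fibril,
    make_fixture,
    metric_series,
    segment_epochs,
)
from fibrilnet.metrics import smooth_series


class TestGraphMetrics:
    def test_free_monomers_average_component_size_one(self):
        m = graph_metrics(AggregationGraph(40), "1-ribbon")
        assert m["avg_component_size"] == 1.0
        assert m["fibril_fraction"] == 0.0
        assert m["oligomer_count"] == 0.0

    def test_ideal_ribbon_metrics(self):
        m = graph_metrics(ideal_fibril("1-ribbon", 10), "1-ribbon")
        assert m["fibril_fraction"] == 1.0
        assert m["fibril_component_count"] == 1.0
        assert m["max_fibril_size"] == 10.0

    def test_oligomers_are_components_smaller_than_eight(self):
        """Component sizes {3, 7, 8, 12}: only 3 and 7 are oligomers."""
        g = AggregationGraph(30)
        start = 0
        for size in (3, 7, 8, 12):
            for k in range(size - 1):
                g.add_edge(start + k, start + k + 1)
            start += size
        m = graph_metrics(g, "3-prism")
        assert m["oligomer_count"] == 2.0
        assert m["avg_component_size"] == 30 / 4

    def test_fraction_times_n_is_total_fibrillar_mass(self):
        g = make_fixture("fibril_with_defect", template="1-ribbon", length=8)
        m = graph_metrics(g, "1-ribbon")
        assert m["fibril_fraction"] * g.n == pytest.approx(8.0)


class TestMetricSeries:
    def test_frozen_trajectory_gives_constant_series(self, params):
        from fibrilnet import Trajectory

        traj = Trajectory(n=12, seed=None, params=None)
        df = metric_series(traj, "1-ribbon")
        assert len(df) == 1
        assert df.avg_component_size.iloc[0] == 1.0

    def test_sequential_growth_has_nondecreasing_fraction(self):
        traj = make_fixture("growth_trajectory", n=20)
        df = metric_series(traj, "1-ribbon", stride=1)
        assert np.all(np.diff(df.fibril_fraction.to_numpy()) >= -1e-12)

    def test_stride_rows_are_a_subset_of_full_recomputation(self, params):
        from fibrilnet import simulate

        traj = simulate(8, params, seed=6, max_events=300)
        full = metric_series(traj, "1-ribbon", stride=1)
        coarse = metric_series(traj, "1-ribbon", stride=25)
        merged = full.merge(coarse, on="event", suffixes=("", "_c"))
        for col in ("avg_component_size", "max_fibril_size", "fibril_fraction"):
            assert np.allclose(merged[col], merged[col + "_c"])


class TestEpochSegmentation:
    def test_boundaries_land_on_planted_frames(self):
        df = make_fixture(
            "metric_curve",
            avg_peak=10,
            nucleation_frame=25,
            count_peak=40,
            maturation_frame=150,
        )
        seg = segment_epochs(df, "1-ribbon", smooth_window=3)
        assert seg.boundary_frames == {
            "Condensation": 10,
            "Local Ordering": 25,
            "Nucleation": 40,
            "Fibril Growth": 150,
        }

    def test_boundaries_match_independent_landmark_computation(self):
        """Recompute each landmark with one-line numpy rules."""
        df = make_fixture("metric_curve")
        w = 3
        seg = segment_epochs(df, "1-ribbon", smooth_window=w)
        avg = smooth_series(df.avg_component_size.to_numpy(), w)
        count = smooth_series(df.fibril_component_count.to_numpy(), w)
        size = smooth_series(df.max_fibril_size.to_numpy(), w)
        assert seg.boundary_frames["Condensation"] == int(np.argmax(avg))
        assert seg.boundary_frames["Local Ordering"] == int(
            np.nonzero(size >= 4)[0][0]
        )
        assert seg.boundary_frames["Nucleation"] == int(np.argmax(count))

    def test_segmentation_is_contiguous_and_covers_time_axis(self):
        df = make_fixture("metric_curve")
        seg = segment_epochs(df, "1-ribbon", smooth_window=3)
        assert seg.epochs[0].t_start == df.time.iloc[0]
        assert seg.epochs[-1].t_end == df.time.iloc[-1]
        for a, b in zip(seg.epochs, seg.epochs[1:]):
            assert a.t_end == b.t_start

    def test_boundaries_invariant_under_time_rescaling(self):
        df = make_fixture("metric_curve")
        scaled = df.copy()
        scaled["time"] = df["time"] * 37.5
        a = segment_epochs(df, "1-ribbon", smooth_window=3)
        b = segment_epochs(scaled, "1-ribbon", smooth_window=3)
        assert a.boundary_frames == b.boundary_frames

    def test_missing_nucleation_reports_undetectable(self):
        df = make_fixture("metric_curve")
        df = df.copy()
        df["max_fibril_size"] = 0.0  # threshold never reached
        with pytest.raises(EpochUndetectableError) as err:
            segment_epochs(df, "1-ribbon", smooth_window=3)
        assert "Local Ordering" in str(err.value)
        assert err.value.found["condensation_end"] == 10

    def test_one_ribbon_pathway_schemes_share_machinery(self):
        df = make_fixture("metric_curve")
        ca = segment_epochs(df, "1-ribbon", scheme="condensate-annealing", smooth_window=3)
        dc = segment_epochs(df, "1-ribbon", scheme="dendrite-consolidation", smooth_window=3)
        assert ca.labels == ["Dimerization", "Condensation", "Annealing", "Maturation"]
        assert dc.labels == [
            "Dimerization",
            "Local Ordering",
            "Fibril Growth",
            "Consolidation",
            "Maturation",
        ]
        assert ca.boundary_frames["Dimerization"] == dc.boundary_frames["Dimerization"]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            segment_epochs(pd.DataFrame(), "1-ribbon")
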