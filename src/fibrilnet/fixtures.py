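"""Deterministic fixture generators: ideal fibrils, joined fibrils,
fibrils with defects, synthetic growth trajectories and metric curves.

These produce the small, fully controlled inputs used throughout the test
suite and the examples; everything is generated programmatically, nothing
is loaded from disk.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .graph import AggregationGraph
from .kinetics import Event, Frame, Trajectory
from .metrics import METRIC_COLUMNS
from .topology import FibrilTemplate, get_template, ideal_fibril

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "ideal_fibril",
    "two_fibrils_joined",
    "fibril_with_defect",
    "growth_trajectory",
    "metric_curve",
)


def make_fixture(kind: str, **spec):
    """Dispatch to a deterministic fixture builder; see FIXTURE_KINDS."""
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}"
        ) from None
    return builder(**spec)


def _ideal(template: Union[str, FibrilTemplate] = "1-ribbon", length: int = 10):
    return ideal_fibril(template, length)


def _two_joined(
    template: Union[str, FibrilTemplate] = "1-ribbon",
    length: int = 10,
    joint: str = "end-end",
):
    """Two disjoint ideal fibrils plus one bridging edge.

    ``joint="end-end"`` bonds a terminal vertex of each fibril;
    ``joint="end-center"`` bonds a terminal vertex of the first to a
    mid-fibril vertex of the second.
    """
    t = get_template(template)
    a = ideal_fibril(t, length)
    n1 = a.n
    g = AggregationGraph(2 * n1)
    for u, v in a.edges():
        g.add_edge(u, v)
        g.add_edge(u + n1, v + n1)
    tail_a = (length - 1) * t.subunit_size  # position 0 of last subunit
    if joint == "end-end":
        g.add_edge(tail_a, n1)  # position 0 of first subunit of B
    elif joint == "end-center":
        mid_b = n1 + (length // 2) * t.subunit_size
        g.add_edge(tail_a, mid_b)
    else:
        raise ValueError(f"unknown joint {joint!r}")
    return g


def _with_defect(
    template: Union[str, FibrilTemplate] = "1-ribbon",
    length: int = 10,
    attach: str = "center",
    n_defect: int = 1,
):
    """An ideal fibril plus a chain of defect monomers bonded to it.

    ``attach="center"`` bonds the first defect to a mid-fibril vertex,
    ``attach="end"`` to a terminal vertex.
    """
    t = get_template(template)
    base = ideal_fibril(t, length)
    n0 = base.n
    g = AggregationGraph(n0 + n_defect)
    for u, v in base.edges():
        g.add_edge(u, v)
    anchor = (length // 2) * t.subunit_size if attach == "center" else 0
    if attach not in ("center", "end"):
        raise ValueError(f"unknown attach {attach!r}")
    prev = anchor
    for k in range(n_defect):
        g.add_edge(prev, n0 + k)
        prev = n0 + k
    return g


def _growth_trajectory(
    n: int = 20,
    dt: float = 1.0,
    frame_interval: int = 5,
):
    """Pure sequential 1-ribbon growth: edge (k, k+1) added at time (k+1)*dt.

    A deterministic event-stream trajectory whose fibril fraction is
    non-decreasing (monomers only ever join the growing fibril).
    """
    if n < 2:
        raise ValueError("need at least 2 monomers")
    traj = Trajectory(n=n, seed=None, params=None, frame_interval=frame_interval)
    g = AggregationGraph(n)
    for k in range(n - 1):
        t = (k + 1) * dt
        g.add_edge(k, k + 1)
        traj.events.append(Event(k, t, k, k + 1, "add"))
        if (k + 1) % frame_interval == 0:
            traj.frames.append(Frame(k + 1, t, g.edge_set()))
    if traj.frames[-1].event_index != n - 1:
        traj.frames.append(Frame(n - 1, (n - 1) * dt, g.edge_set()))
    traj.end_time = (n - 1) * dt
    return traj


def _metric_curve(
    n_frames: int = 200,
    avg_peak: int = 10,
    nucleation_frame: int = 25,
    count_peak: int = 40,
    maturation_frame: int = 150,
    threshold: int = 4,
    dt: float = 1.0,
):
    """Synthetic metric series with planted epoch landmarks.

    Constructed so that, after a window-3 centered moving average, the
    five-epoch boundary rules land exactly on the planted frames:
    ``avg_component_size`` peaks (symmetrically) at ``avg_peak``,
    ``max_fibril_size`` first reaches ``threshold`` at ``nucleation_frame``,
    ``fibril_component_count`` peaks at ``count_peak``, and both
    ``fibril_fraction`` and ``max_fibril_size`` converge (to within a 5%
    trailing fluctuation) exactly from ``maturation_frame`` on.
    """
    if not (0 < avg_peak < nucleation_frame < count_peak < maturation_frame < n_frames - 2):
        raise ValueError("planted frames must be strictly ordered inside the series")
    k = np.arange(n_frames, dtype=float)

    # symmetric tent around avg_peak, then a low plateau
    avg = np.where(
        k <= avg_peak,
        1.0 + k,
        np.maximum(1.0 + avg_peak - (k - avg_peak), 2.0),
    )

    # max fibril size: 0, a 2*threshold jump at the nucleation frame, a
    # pre-maturation plateau, then the final jump (gap sized so that the
    # smoothed trailing fluctuation first drops under 5% exactly at
    # maturation_frame: (M - M_pre) / (3 M) in [tol, 2*tol))
    m_final = 50.0
    m_pre = 44.0
    size = np.zeros(n_frames)
    size[k >= nucleation_frame] = 2.0 * threshold
    ramp = (k >= count_peak) & (k < maturation_frame)
    size[ramp] = m_pre
    size[k >= maturation_frame] = m_final

    count = np.where(
        k <= count_peak,
        k / 4.0,
        np.maximum(count_peak / 4.0 - (k - count_peak) / 4.0, 2.0),
    )

    frac_final = 0.8
    frac_pre = frac_final - 3 * 0.04 * frac_final  # same trailing-gap sizing
    frac = np.minimum(frac_pre * k / count_peak, frac_pre)
    frac[k >= maturation_frame] = frac_final

    df = pd.DataFrame(
        {
            "time": k * dt,
            "avg_component_size": avg,
            "max_fibril_size": size,
            "fibril_component_count": count,
            "fibril_fraction": frac,
            "oligomer_count": np.zeros(n_frames),
        }
    )
    return df[list(METRIC_COLUMNS)]


_BUILDERS = {
    "ideal_fibril": _ideal,
    "two_fibrils_joined": _two_joined,
    "fibril_with_defect": _with_defect,
    "growth_trajectory": _growth_trajectory,
    "metric_curve": _metric_curve,
}
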