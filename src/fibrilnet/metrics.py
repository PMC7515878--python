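"""Per-frame aggregation metrics and epoch segmentation of trajectories.

The mechanism of fibril formation is read off a small set of per-frame
network measures:

* average component size — mean monomer count per aggregate (n divided by
  the number of connected components, free monomers included);
* maximum induced fibril component size and induced fibril component
  count — from :func:`fibrilnet.topology.induced_fibrillar_components`;
* fibril fraction — fraction of all monomers bound within a fibrillar
  component;
* oligomer count — connected components with 2 <= size < 8 (free monomers
  are not oligomers).

Epoch segmentation marks the phases of self-assembly on the smoothed
metric series.  The five-epoch scheme used by the higher-order topologies:
Condensation ends at the maximum of average component size; Local Ordering
ends when the maximum induced fibril size first reaches the nucleation
threshold (start of Nucleation); Fibril Growth starts at the maximum of
the induced fibril component count; Maturation starts when both fibril
fraction and max fibril size have converged (stay within ``conv_tol``
relative fluctuation through the end of the series).  Two alternative
label schemes cover the 1-ribbon pathways (condensate annealing and
dendrite consolidation), sharing the same boundary machinery plus an
initial dimerization epoch that ends when the average component size
first reaches 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .graph import AggregationGraph
from .kinetics import Trajectory
from .topology import (
    FibrilTemplate,
    get_template,
    induced_fibrillar_components,
    nucleation_threshold,
)

__all__ = [
    "METRIC_COLUMNS",
    "graph_metrics",
    "metric_series",
    "Epoch",
    "EpochSegmentation",
    "EpochUndetectableError",
    "segment_epochs",
    "SCHEMES",
]

OLIGOMER_MAX = 8  # components of size < 8 (and >= 2) are oligomers

METRIC_COLUMNS = (
    "time",
    "avg_component_size",
    "max_fibril_size",
    "fibril_component_count",
    "fibril_fraction",
    "oligomer_count",
)


def graph_metrics(
    g: AggregationGraph, template: Union[str, FibrilTemplate], mode: str = "partial"
) -> dict[str, float]:
    """Single-frame aggregation metrics (no time column)."""
    t = get_template(template)
    comps = g.connected_components()
    fib = induced_fibrillar_components(g, t, mode=mode)
    n_fibrillar = sum(c.size for c in fib.components)
    return {
        "avg_component_size": g.n / len(comps),
        "max_fibril_size": float(fib.max_size),
        "fibril_component_count": float(fib.count),
        "fibril_fraction": n_fibrillar / g.n,
        "oligomer_count": float(
            sum(1 for c in comps if 2 <= len(c) < OLIGOMER_MAX)
        ),
    }


def metric_series(
    traj: Trajectory,
    template: Union[str, FibrilTemplate],
    stride: int = 1,
    mode: str = "partial",
) -> pd.DataFrame:
    """Metrics along a trajectory, one row per sampled frame.

    Frames are sampled every ``stride`` events (event 0 and the final event
    are always included).  Columns are :data:`METRIC_COLUMNS`.
    """
    t = get_template(template)
    rows = []
    for k, time, g in traj.iter_states(stride):
        rec = graph_metrics(g, t, mode=mode)
        rec["time"] = time
        rec["event"] = k
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[list(METRIC_COLUMNS) + ["event"]]


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    label: str
    t_start: float
    t_end: float


@dataclass
class EpochSegmentation:
    """Contiguous labeled intervals covering a trajectory's time axis."""

    scheme: str
    epochs: list[Epoch]
    boundary_frames: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.label, e.t_start, e.t_end) for e in self.epochs],
            columns=["label", "t_start", "t_end"],
        )

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]


class EpochUndetectableError(ValueError):
    """Raised when a scheme's boundary events are missing or out of order."""

    def __init__(self, message: str, found: dict[str, int | None]):
        self.found = found
        super().__init__(f"{message}; boundaries found: {found}")


def smooth_series(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinking windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(x).rolling(window, center=True, min_periods=1).mean()
    return s.to_numpy()


def _first_at_least(x: np.ndarray, threshold: float) -> int | None:
    hits = np.nonzero(x >= threshold)[0]
    return int(hits[0]) if hits.size else None


def _convergence_start(
    series_list: list[np.ndarray], start: int, conv_tol: float
) -> int | None:
    """Earliest frame from which every series stays within conv_tol
    relative fluctuation through the end."""
    n = len(series_list[0])
    eps = 1e-12

    def converged_from(m: int) -> bool:
        for x in series_list:
            tail = x[m:]
            scale = max(abs(float(tail.mean())), eps)
            if (tail.max() - tail.min()) / scale > conv_tol:
                return False
        return True

    # scan forward for the earliest frame; fluctuation over [m, end] is
    # non-increasing in m only per-series-max, so a simple scan is safest
    for m in range(start, n):
        if converged_from(m):
            return m
    return None


SCHEMES = ("five-epoch", "condensate-annealing", "dendrite-consolidation")


def segment_epochs(
    series: pd.DataFrame,
    template: Union[str, FibrilTemplate],
    scheme: str = "five-epoch",
    smooth_window: int | None = None,
    conv_tol: float = 0.05,
) -> EpochSegmentation:
    """Segment a metric series into the scheme's ordered epochs.

    Boundaries are computed on the smoothed series (centered moving
    average; default window 1% of frames, minimum 3) and are functions of
    frame order and values only, so they are invariant under uniform
    rescaling of the time axis.  Raises :class:`EpochUndetectableError`
    when a boundary never occurs or the boundaries fall out of scheme
    order.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; known: {SCHEMES}")
    if len(series) == 0:
        raise ValueError("empty metric series")
    t = get_template(template)
    thr = nucleation_threshold(t)
    n = len(series)
    if smooth_window is None:
        smooth_window = max(3, round(0.01 * n))

    times = series["time"].to_numpy()
    avg = smooth_series(series["avg_component_size"].to_numpy(), smooth_window)
    max_size = smooth_series(series["max_fibril_size"].to_numpy(), smooth_window)
    count = smooth_series(
        series["fibril_component_count"].to_numpy(), smooth_window
    )
    frac = smooth_series(series["fibril_fraction"].to_numpy(), smooth_window)

    b: dict[str, int | None] = {}
    b["condensation_end"] = int(np.argmax(avg))  # first occurrence on ties
    b["nucleation_start"] = _first_at_least(max_size, thr)
    b["growth_start"] = int(np.argmax(count))
    conv_from = b["growth_start"] if b["growth_start"] is not None else 0
    b["maturation_start"] = _convergence_start([frac, max_size], conv_from, conv_tol)
    b["dimerization_end"] = _first_at_least(avg, 2.0)

    def frames_to_epochs(labels: list[str], frames: list[int | None]) -> EpochSegmentation:
        missing = [
            lab for lab, f in zip(labels[:-1], frames) if f is None
        ]
        if missing:
            raise EpochUndetectableError(
                f"boundary for epoch(s) {missing} never occurs", dict(b)
            )
        ordered = all(
            frames[i] <= frames[i + 1] for i in range(len(frames) - 1)
        )
        if not ordered:
            raise EpochUndetectableError(
                "boundary events occur out of scheme order", dict(b)
            )
        cuts = [times[0]] + [times[f] for f in frames] + [times[-1]]
        epochs = [
            Epoch(lab, cuts[i], cuts[i + 1]) for i, lab in enumerate(labels)
        ]
        frame_map = {
            lab: f for lab, f in zip(labels[:-1], frames)
        }
        return EpochSegmentation(scheme, epochs, frame_map)

    if scheme == "five-epoch":
        labels = [
            "Condensation",
            "Local Ordering",
            "Nucleation",
            "Fibril Growth",
            "Maturation",
        ]
        frames = [
            b["condensation_end"],
            b["nucleation_start"],
            b["growth_start"],
            b["maturation_start"],
        ]
    elif scheme == "condensate-annealing":
        labels = ["Dimerization", "Condensation", "Annealing", "Maturation"]
        frames = [
            b["dimerization_end"],
            b["condensation_end"],
            b["maturation_start"],
        ]
    else:  # dendrite-consolidation
        labels = [
            "Dimerization",
            "Local Ordering",
            "Fibril Growth",
            "Consolidation",
            "Maturation",
        ]
        frames = [
            b["dimerization_end"],
            b["nucleation_start"],
            b["growth_start"],
            b["maturation_start"],
        ]
    return frames_to_epochs(labels, frames)
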