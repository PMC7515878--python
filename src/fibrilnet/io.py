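"""Serialization: parameter files, edge lists, GraphML, event-stream
trajectories, and metric/epoch/census tables.

The canonical trajectory format is a TSV event stream — lossless for
single-toggle dynamics and compact.  Floating-point times are written with
``repr`` so round trips are bit-exact.  All writers stamp a provenance
header (package version, parameter hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import __version__
from .graph import AggregationGraph
from .kinetics import Event, Frame, Trajectory
from .model import PHI_KEYS, ModelParams

__all__ = [
    "ParamsError",
    "TrajectoryFormatError",
    "load_params",
    "save_params",
    "params_hash",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "read_trajectory",
    "write_trajectory",
    "read_table",
    "write_table",
]

PathLike = Union[str, Path]


class ParamsError(ValueError):
    pass


class TrajectoryFormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

_OPTIONAL_DEFAULTS = {"k_B": 1.0, "A": 1.0, "ref_measure": "counting"}


def load_params(path: PathLike) -> ModelParams:
    """Load model parameters from a YAML or JSON file.

    All nine ``phi_*`` keys plus ``T`` are required; ``k_B``, ``A`` and
    ``ref_measure`` default to 1, 1 and ``"counting"``.  Missing keys and
    non-numeric values raise :class:`ParamsError` naming the key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ParamsError(f"parameter file {path} does not contain a mapping")

    kwargs = {}
    for key in (*PHI_KEYS, "T"):
        if key not in raw:
            raise ParamsError(f"parameter file {path} is missing key {key!r}")
        value = raw[key]
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParamsError(
                f"parameter {key!r} must be numeric, got {value!r}"
            )
        kwargs[key] = float(value)
    for key, default in _OPTIONAL_DEFAULTS.items():
        value = raw.get(key, default)
        if key == "ref_measure":
            if not isinstance(value, str):
                raise ParamsError(f"parameter 'ref_measure' must be a string")
        elif isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParamsError(f"parameter {key!r} must be numeric, got {value!r}")
        else:
            value = float(value)
        kwargs[key] = value
    unknown = set(raw) - set(kwargs)
    if unknown:
        raise ParamsError(f"unknown parameter keys {sorted(unknown)} in {path}")
    return ModelParams(**kwargs)


def save_params(params: ModelParams, path: PathLike) -> None:
    path = Path(path)
    data = params.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def params_hash(params: ModelParams | None) -> str:
    """Short stable digest of a parameter set, for output provenance."""
    if params is None:
        return "none"
    payload = json.dumps(params.as_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def write_edge_list(g: AggregationGraph, path: PathLike) -> None:
    lines = [f"# n={g.n}"]
    lines += [f"{u}\t{v}" for u, v in sorted(g.edges())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: PathLike) -> AggregationGraph:
    lines = Path(path).read_text().splitlines()
    n = None
    edges = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "n=" in line and n is None:
                n = int(line.split("n=")[1].split()[0])
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TrajectoryFormatError(f"malformed edge line {line!r}", ln)
        edges.append((int(parts[0]), int(parts[1])))
    if n is None:
        raise TrajectoryFormatError("edge list missing '# n=<N>' header")
    return AggregationGraph(n, edges)


def write_graphml(g: AggregationGraph, path: PathLike) -> None:
    import networkx as nx

    nx.write_graphml(g.to_networkx(), str(path))


def read_graphml(path: PathLike) -> AggregationGraph:
    import networkx as nx

    return AggregationGraph.from_networkx(nx.read_graphml(str(path)))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    """Write the canonical TSV event stream.

    Per-event records ``E<TAB>index<TAB>time<TAB>u<TAB>v<TAB>add|del``,
    snapshot blocks ``S<TAB>event<TAB>time`` followed by ``s<TAB>u<TAB>v``
    edge lines, and a trailing count footer used to detect truncation.
    """
    if traj.params is not None and not traj.params.counting_measure:
        raise ValueError(
            "trajectories with a custom (callable) reference measure "
            "cannot be serialized"
        )
    out = [
        f"# fibrilnet trajectory v1 (version={__version__})",
        f"# n={traj.n}",
        f"# seed={traj.seed}",
        f"# params_hash={params_hash(traj.params)}",
        f"# frame_interval={traj.frame_interval}",
        f"# end_time={traj.end_time!r}",
    ]
    if traj.params is not None:
        out.append(f"# params_json={json.dumps(traj.params.as_dict(), sort_keys=True)}")
    for ev in traj.events:
        out.append(f"E\t{ev.index}\t{ev.time!r}\t{ev.u}\t{ev.v}\t{ev.kind}")
    for fr in traj.frames:
        out.append(f"S\t{fr.event_index}\t{fr.time!r}")
        out += [f"s\t{u}\t{v}" for u, v in sorted(fr.edges)]
    out.append(f"# end events={len(traj.events)} frames={len(traj.frames)}")
    Path(path).write_text("\n".join(out) + "\n")


def read_trajectory(path: PathLike) -> Trajectory:
    """Read a trajectory; bit-exact inverse of :func:`write_trajectory`."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    events: list[Event] = []
    frames: list[Frame] = []
    current_snapshot: tuple[int, float, list] | None = None
    footer = None

    def flush_snapshot():
        nonlocal current_snapshot
        if current_snapshot is not None:
            idx, t, edges = current_snapshot
            frames.append(Frame(idx, t, frozenset(edges)))
            current_snapshot = None

    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("end "):
                footer = (body, ln)
                continue
            for token in body.split():
                if "=" in token:
                    k, _, v = token.partition("=")
                    meta.setdefault(k, v)
            continue
        parts = line.split("\t")
        tag = parts[0]
        try:
            if tag == "E":
                flush_snapshot()
                _, idx, t, u, v, kind = parts
                if kind not in ("add", "del"):
                    raise ValueError(f"bad event kind {kind!r}")
                events.append(Event(int(idx), float(t), int(u), int(v), kind))
            elif tag == "S":
                flush_snapshot()
                _, idx, t = parts
                current_snapshot = (int(idx), float(t), [])
            elif tag == "s":
                if current_snapshot is None:
                    raise ValueError("edge line outside snapshot block")
                _, u, v = parts
                current_snapshot[2].append((int(u), int(v)))
            else:
                raise ValueError(f"unknown record tag {tag!r}")
        except (ValueError, IndexError) as exc:
            raise TrajectoryFormatError(f"malformed record: {exc}", ln) from exc
    flush_snapshot()

    if "n" not in meta:
        raise TrajectoryFormatError("trajectory missing '# n=<N>' header")
    if footer is None:
        raise TrajectoryFormatError(
            "trajectory truncated: missing end footer", len(lines)
        )
    body, ln = footer
    declared = dict(
        token.partition("=")[::2] for token in body.split()[1:]
    )
    if int(declared.get("events", -1)) != len(events):
        raise TrajectoryFormatError(
            f"trajectory truncated: footer declares {declared.get('events')} "
            f"events, found {len(events)}",
            ln,
        )
    if int(declared.get("frames", -1)) != len(frames):
        raise TrajectoryFormatError(
            f"trajectory truncated: footer declares {declared.get('frames')} "
            f"frames, found {len(frames)}",
            ln,
        )

    params = None
    if "params_json" in meta:
        # params_json value may contain spaces; re-extract from raw line
        for line in lines:
            if line.startswith("# params_json="):
                params = ModelParams(
                    **json.loads(line[len("# params_json=") :])
                )
                break
    end_time = meta.get("end_time")
    seed = meta.get("seed")
    return Trajectory(
        n=int(meta["n"]),
        seed=None if seed in (None, "None") else int(seed),
        params=params,
        events=events,
        frames=frames,
        frame_interval=int(meta.get("frame_interval", 1000)),
        end_time=None if end_time in (None, "None") else float(end_time),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame, path: PathLike, meta: dict | None = None
) -> None:
    """CSV with '#'-prefixed provenance header lines."""
    header = {"version": __version__}
    header.update(meta or {})
    lines = [f"# {k}={v}" for k, v in header.items()]
    Path(path).write_text(
        "\n".join(lines) + "\n" + df.to_csv(index=False)
    )


def read_table(path: PathLike) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                k, _, v = body.partition("=")
                meta[k] = v
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, meta
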