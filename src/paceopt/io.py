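"""File I/O and run configuration.

Velocity traces are CSV files with header ``time_s,speed_mps``; split
tables are CSV with ``distance_m,cumulative_time_s`` where times may be
plain seconds or the "m:ss.cc" strings used in official results (e.g.
"3:32.76" parses to 212.76 s).  Three official 1500 m split tables
(Ingebrigtsen: Munich 2022, Eugene 2022, Chorzow 2023) ship with the
package as fitting targets.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .identify import ObservedRace, SearchSpace
from .synthetic import VelocityTrace
from .track import TrackGeometry, build_track

__all__ = [
    "read_trace",
    "write_trace",
    "read_splits",
    "write_splits",
    "parse_time",
    "format_time",
    "official_split_table",
    "OFFICIAL_RACES",
    "RunConfig",
    "read_search_space",
]

#: official 1500 m races shipped as package data (world-class championship
#: and Diamond League performances with published 100 m splits)
OFFICIAL_RACES = ("munich_2022", "eugene_2022", "chorzow_2023")


def parse_time(value) -> float:
    """Parse a time given as seconds or an "m:ss.cc" string to seconds."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if ":" in text:
        minutes, seconds = text.split(":")
        return int(minutes) * 60.0 + float(seconds)
    return float(text)


def format_time(seconds: float) -> str:
    """Format seconds as "m:ss.cc"."""
    minutes = int(seconds // 60)
    return f"{minutes}:{seconds - 60 * minutes:05.2f}"


def write_trace(trace: VelocityTrace, path: str | Path) -> None:
    """Write a velocity trace as CSV (full precision) with JSON sidecar."""
    trace.to_csv(path)


def read_trace(path: str | Path) -> VelocityTrace:
    """Read a 10 Hz-style velocity trace CSV (``time_s,speed_mps``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=float)
    for col in ("time_s", "speed_mps"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty trace")
    if len(df) < 2:
        raise ValueError(f"{path}: a trace needs at least two samples")
    t = df["time_s"].to_numpy()
    v = df["speed_mps"].to_numpy()
    bad = np.nonzero(v < 0)[0]
    if bad.size:
        raise ValueError(f"{path}: negative speed at line {bad[0] + 2}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.nonzero(dt <= 0)[0][0]) + 3
        raise ValueError(f"{path}: non-monotone time at line {line}")
    step = dt[0]
    off = np.nonzero(np.abs(dt - step) > 1e-6)[0]
    if off.size:
        raise ValueError(f"{path}: non-uniform time step at line {int(off[0]) + 3}")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("sample_rate", None)
    return VelocityTrace(times=t, speeds=v, sample_rate=1.0 / step, metadata=meta)


def write_splits(splits, path: str | Path) -> None:
    """Write (distance, cumulative time) pairs as CSV in plain seconds
    plus a formatted "m:ss.cc" convenience column."""
    df = pd.DataFrame(splits, columns=["distance_m", "cumulative_time_s"])
    df["cumulative_time"] = df["cumulative_time_s"].map(format_time)
    df.to_csv(path, index=False)


def _validate_splits(d, t, origin: str):
    if np.any(np.diff(d) <= 0):
        raise ValueError(f"{origin}: split distances must be strictly increasing")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{origin}: cumulative times must be strictly increasing")


def read_splits(
    path: str | Path,
    track: TrackGeometry | None = None,
    event_distance: float | None = None,
) -> ObservedRace:
    """Read a split table CSV into an :class:`ObservedRace` (splits mode).

    If no track is given, a lane-1 track for the table's final distance is
    built (400 or 1500).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "distance_m" not in df.columns or "cumulative_time_s" not in df.columns:
        raise ValueError(f"{path}: need columns distance_m, cumulative_time_s")
    if len(df) == 0:
        raise ValueError(f"{path}: empty split table")
    d = df["distance_m"].astype(float).to_numpy()
    t = np.array([parse_time(x) for x in df["cumulative_time_s"]])
    _validate_splits(d, t, str(path))
    D = event_distance if event_distance is not None else float(d[-1])
    if track is None:
        track = build_track(int(round(D)), lane=1)
    return ObservedRace(
        event_distance=D,
        track=track,
        splits=tuple((float(x), float(y)) for x, y in zip(d, t)),
    )


def official_split_table(race: str, track: TrackGeometry | None = None) -> ObservedRace:
    """Load one of the packaged official 1500 m split tables.

    ``race`` is one of :data:`OFFICIAL_RACES`.  Splits run from 200 m to
    the finish in 100 m steps; the Chorzow race was officially reported to
    one decimal place.
    """
    if race not in OFFICIAL_RACES:
        raise ValueError(f"unknown race {race!r}; choose from {OFFICIAL_RACES}")
    ref = importlib.resources.files("paceopt.data") / f"{race}_1500m_splits.csv"
    with importlib.resources.as_file(ref) as p:
        return read_splits(p, track=track)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Every CLI run writes its resolved config next to its outputs so that
    the run is reproducible from that file and the seed alone.
    """

    event: int = 1500
    lane: int = 1
    n_nodes: int = 300
    tol: float = 1e-6
    swarm_size: int = 24
    iterations: int = 40
    polish_evals: int = 0
    seed: int = 0
    bounds_file: str | None = None
    params_file: str | None = None
    observation_file: str | None = None
    out_dir: str = "."
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event not in (400, 1500):
            raise ValueError(f"event must be 400 or 1500, got {self.event}")
        if not 1 <= self.lane <= 9:
            raise ValueError(f"lane must be in 1..9, got {self.lane}")
        if self.n_nodes < 30:
            raise ValueError("n_nodes must be at least 30")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.swarm_size < 2 or self.iterations < 1:
            raise ValueError("swarm_size >= 2 and iterations >= 1 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(data.pop("extras", {}) or {})
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extras=extras)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_search_space(path: str | Path) -> SearchSpace:
    """Load a :class:`SearchSpace` from YAML: ``bounds: {name: [lo, hi]}``
    plus optional ``fixed: {name: value}``."""
    data = yaml.safe_load(Path(path).read_text())
    bounds = {k: (float(v[0]), float(v[1])) for k, v in data.get("bounds", {}).items()}
    fixed = {k: float(v) for k, v in data.get("fixed", {}).items()}
    return SearchSpace(bounds=bounds, fixed=fixed)
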