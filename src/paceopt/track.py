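"""Lane- and event-specific race paths on a standard 400 m outdoor track.

A standard outdoor track consists of two 84 m straights joined by two
semicircular bends.  The lane-1 measurement line runs 0.30 m outside the
kerb, giving a bend radius of 36.5 m; each bend is 116 m of arc along that
line.  A race path is represented as an ordered list of constant-curvature
segments, so the curvature profile kappa(s) is piecewise constant: zero on
the straights and 1/R on the bends, where R grows with the lane number.

The 400 m is run entirely in lanes and starts on the first bend with a
staggered start: lane n's first bend is shortened by the stagger
2*pi*w*(n-1) so that every lane covers exactly 400 m to the common finish.
The 1500 m is run on lane 1 and starts from a curved line at the beginning
of the back straight; here that start is modelled as a short bend stub of
arc length D - 3.75 laps' worth of segments (16 m) so the total is exactly
1500 m and the finish falls at the bend/home-straight junction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "TrackSegment",
    "TrackGeometry",
    "build_track",
    "curvature_at",
    "STRAIGHT_LENGTH",
    "BEND_LENGTH",
    "BASE_BEND_RADIUS",
    "LANE_WIDTH",
]

#: length of each straight on a standard outdoor track (m)
STRAIGHT_LENGTH = 84.0
#: arc length of each lane-1 bend along the measurement line (m)
BEND_LENGTH = 116.0
#: lane-1 bend radius: 0.30 m outside the kerb (m)
BASE_BEND_RADIUS = 36.5
#: World Athletics standard lane width (m)
LANE_WIDTH = 1.22


@dataclass(frozen=True)
class TrackSegment:
    """A constant-curvature piece of the race path.

    ``curvature`` is 0 on straights and ``1/R_lane`` on bends.
    """

    length: float
    curvature: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment length must be > 0, got {self.length}")
        if self.curvature < 0:
            raise ValueError(f"curvature must be >= 0, got {self.curvature}")


@dataclass(frozen=True)
class TrackGeometry:
    """A race path of exact event distance as ordered constant-curvature segments."""

    event_distance: float
    lane: int
    segments: tuple[TrackSegment, ...]
    bend_radius: float
    lane_width: float = LANE_WIDTH
    base_radius: float = BASE_BEND_RADIUS
    _cumulative: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        total = math.fsum(seg.length for seg in self.segments)
        if abs(total - self.event_distance) > 1e-9:
            raise ValueError(
                f"segment lengths sum to {total!r}, expected {self.event_distance!r}"
            )
        cum = [0.0]
        for seg in self.segments:
            cum.append(cum[-1] + seg.length)
        object.__setattr__(self, "_cumulative", tuple(cum))

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Cumulative segment boundaries, starting at 0 and ending at D."""
        return self._cumulative

    def curvature_at(self, s: float) -> float:
        """Curvature (1/m) of the segment containing arc position ``s``.

        Right-continuous at interior boundaries; at ``s = D`` the final
        segment's curvature is returned.
        """
        if s < 0 or s > self.event_distance:
            raise ValueError(
                f"s={s} outside [0, {self.event_distance}]"
            )
        # right-continuous: boundary belongs to the following segment
        for i, seg in enumerate(self.segments):
            if s < self._cumulative[i + 1]:
                return seg.curvature
        return self.segments[-1].curvature

    def curvature_profile(self, s_grid) -> "pd.Series | list[float]":
        """Vectorized curvature lookup (returns a plain list for iterables)."""
        return [self.curvature_at(float(s)) for s in s_grid]

    # -- serialization ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write segments as CSV with a JSON metadata sidecar ``<path>.json``."""
        path = Path(path)
        df = pd.DataFrame(
            {
                "segment_index": range(len(self.segments)),
                "length_m": [seg.length for seg in self.segments],
                "curvature_per_m": [seg.curvature for seg in self.segments],
            }
        )
        df.to_csv(path, index=False)
        meta = {
            "event": self.event_distance,
            "lane": self.lane,
            "lane_width": self.lane_width,
            "base_radius": self.base_radius,
            "bend_radius": self.bend_radius,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackGeometry":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        segments = tuple(
            TrackSegment(length=row.length_m, curvature=row.curvature_per_m)
            for row in df.itertuples()
        )
        return cls(
            event_distance=float(meta["event"]),
            lane=int(meta["lane"]),
            segments=segments,
            bend_radius=float(meta["bend_radius"]),
            lane_width=float(meta["lane_width"]),
            base_radius=float(meta["base_radius"]),
        )


def _lane_radius(lane: int, lane_width: float, base_radius: float) -> float:
    return base_radius + lane_width * (lane - 1)


def build_track(
    event: int,
    lane: int = 1,
    lane_width: float = LANE_WIDTH,
    base_radius: float = BASE_BEND_RADIUS,
    straight_length: float = STRAIGHT_LENGTH,
    bend_length: float = BEND_LENGTH,
) -> TrackGeometry:
    """Build the race path for a 400 m (any lane) or 1500 m (lane 1) event.

    The 400 m path starts on the first bend and alternates bend/straight.
    For lane ``n`` the bend curvature is ``1/(R0 + w*(n-1))`` and the full
    bend arc is ``bend_length + pi*w*(n-1)``; the stagger ``2*pi*w*(n-1)``
    is removed from the first bend so every lane runs exactly 400 m.

    The 1500 m path (lane 1 only) starts from the curved start line at the
    head of the back straight: a 16 m bend stub, then straight/bend
    alternation through 3.75 laps to the common finish.

    Parameters
    ----------
    event:
        Race distance, 400 or 1500 (m).
    lane:
        Lane number, 1-9.  The 1500 m is not run in lanes; only lane 1 is
        accepted for it.
    lane_width, base_radius:
        Lane width w (m) and lane-1 bend radius R0 (m).
    """
    if event not in (400, 1500):
        raise ValueError(f"event must be 400 or 1500, got {event}")
    if not 1 <= lane <= 9:
        raise ValueError(f"lane must be in 1..9, got {lane}")
    if lane_width <= 0 or base_radius <= 0:
        raise ValueError("lane width and base radius must be positive")

    radius = _lane_radius(lane, lane_width, base_radius)
    kappa = 1.0 / radius

    if event == 400:
        stagger = 2.0 * math.pi * lane_width * (lane - 1)
        full_bend = bend_length + math.pi * lane_width * (lane - 1)
        first_bend = full_bend - stagger
        if first_bend <= 0:
            raise ValueError("stagger exceeds the first bend for this geometry")
        segments = (
            TrackSegment(first_bend, kappa),
            TrackSegment(straight_length, 0.0),
            TrackSegment(full_bend, kappa),
            TrackSegment(straight_length, 0.0),
        )
        return TrackGeometry(400.0, lane, segments, radius, lane_width, base_radius)

    # 1500 m: lane 1 only, curved start line at the head of the back straight
    if lane != 1:
        raise ValueError("the 1500 m is not run in lanes; lane must be 1")
    lap = 2.0 * (bend_length + straight_length)
    stub = 1500.0 - 3.0 * lap - 2.0 * straight_length - bend_length
    segments = [
        TrackSegment(stub, kappa),
        TrackSegment(straight_length, 0.0),
        TrackSegment(bend_length, kappa),
        TrackSegment(straight_length, 0.0),
    ]
    for _ in range(3):
        segments.append(TrackSegment(bend_length, kappa))
        segments.append(TrackSegment(straight_length, 0.0))
        segments.append(TrackSegment(bend_length, kappa))
        segments.append(TrackSegment(straight_length, 0.0))
    return TrackGeometry(1500.0, 1, tuple(segments), radius, lane_width, base_radius)


def curvature_at(track: TrackGeometry, s: float) -> float:
    """Module-level alias for :meth:`TrackGeometry.curvature_at`."""
    return track.curvature_at(s)
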