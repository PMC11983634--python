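"""Per-nozzle spray decision: lane grid, cluster merging, edge events.

The camera view is divided into one region per nozzle along the lane
axis. Detection boxes are assigned to every lane they overlap, their
travel-axis intervals are dilated by half the minimum valve-respondable
spacing ``d_min`` and unioned (a one-dimensional morphological closing),
and each lane keeps a binary determination value: 1 while any merged
interval overlaps the judgment band, else 0. The 0->1 and 1->0
transitions are the edge events that the hysteresis controller converts
into delayed valve open/close commands.

Merging embodies the physical limit of the solenoid valve: weeds closer
along travel than the distance the sprayer covers in one valve
open/close cycle cannot be serviced as separate bursts, so their
intervals become one continuous spray target. Gaps of at least ``d_min``
are preserved and yield separate bursts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from spotspray.detection import DetectionBox

__all__ = [
    "GeometryConfig",
    "ResponseConfig",
    "LaneGridState",
    "EdgeEvent",
    "assign_lanes",
    "expand_and_merge",
    "update_grid",
]

logger = logging.getLogger(__name__)

Interval = tuple[float, float]


@dataclass(frozen=True)
class GeometryConfig:
    """Fixed geometry of the camera view, lane grid and nozzle bar.

    All lengths in meters. ``grid_y`` places the judgment band inside the
    camera view (world travel axis); ``L1`` is the distance from the
    downstream edge of the band to the nozzle line. The default 10 lanes
    of 0.23 m mirror ten fan nozzles whose 30-degree cone covers 23 cm at
    the working height, with ``nozzle_overlap`` of 1.5 cm per side against
    leakage at lane seams.
    """

    n_lanes: int = 10
    lane_width: float = 0.23
    view_len: float = 1.0
    grid_y: float = 0.93
    grid_depth: float = 0.02
    L1: float = 0.20
    nozzle_overlap: float = 0.015

    def __post_init__(self) -> None:
        if self.n_lanes < 1:
            raise ValueError("n_lanes must be >= 1")
        if self.lane_width <= 0:
            raise ValueError("lane_width must be > 0")
        if self.L1 <= 0:
            raise ValueError("L1 must be > 0")
        if not (0 <= self.grid_y and self.grid_y + self.grid_depth <= self.view_len):
            raise ValueError("judgment band must lie inside the camera view")

    @property
    def width(self) -> float:
        return self.n_lanes * self.lane_width

    @property
    def grid_region(self) -> Interval:
        return (self.grid_y, self.grid_y + self.grid_depth)

    @property
    def nozzle_y(self) -> float:
        """World travel-axis position of the nozzle line."""
        return self.grid_y + self.grid_depth + self.L1

    def lane_span(self, lane: int) -> Interval:
        return (lane * self.lane_width, (lane + 1) * self.lane_width)


@dataclass(frozen=True)
class ResponseConfig:
    """Valve responsiveness: the smallest travel-axis gap between targets
    the valve can service as separate bursts.

    Not a datasheet number — it follows from the valve's open/close cycling
    frequency and the nominal speed: ``d_min = v_nominal / f_valve``
    (0.5 m/s at 10 Hz gives the 0.05 m default).
    """

    d_min: float = 0.05

    def __post_init__(self) -> None:
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")

    @classmethod
    def from_valve(cls, v_nominal: float = 0.5, f_valve: float = 10.0) -> "ResponseConfig":
        return cls(d_min=v_nominal / f_valve)


@dataclass(frozen=True)
class LaneGridState:
    """One lane's binary determination plus its active merged intervals."""

    lane: int
    determination: int = 0
    active_intervals: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.determination not in (0, 1):
            raise ValueError("determination must be 0 or 1")
        if (self.determination == 1) != (len(self.active_intervals) > 0):
            raise ValueError("determination must be 1 iff active intervals exist")


@dataclass(frozen=True)
class EdgeEvent:
    """A determination transition: rising (0->1) or falling (1->0),
    stamped with the time and the speed sample ``v0`` current at that time."""

    lane: int
    kind: str
    t: float
    v0: float

    def __post_init__(self) -> None:
        if self.kind not in ("rising", "falling"):
            raise ValueError("kind must be 'rising' or 'falling'")


def assign_lanes(
    boxes: Sequence[DetectionBox], geom: GeometryConfig
) -> list[list[Interval]]:
    """Distribute boxes' travel intervals to every lane they overlap.

    Lanes are closed intervals, so a box whose edge sits exactly on a lane
    boundary lands in both adjacent lanes — spraying twice beats leaking
    at a seam. A box entirely outside the lane range is dropped with a
    warning.
    """
    out: list[list[Interval]] = [[] for _ in range(geom.n_lanes)]
    for box in boxes:
        x0, x1 = box.lane_span
        if x1 < 0 or x0 > geom.width:
            logger.warning(
                "detection box lane span (%.3f, %.3f) outside lane range [0, %.3f]; ignored",
                x0, x1, geom.width,
            )
            continue
        first = max(0, int(np.floor(x0 / geom.lane_width)))
        last = min(geom.n_lanes - 1, int(np.floor(x1 / geom.lane_width)))
        # a box edge exactly on a boundary also touches the lane below it
        if first > 0 and x0 == first * geom.lane_width:
            first -= 1
        for lane in range(first, last + 1):
            out[lane].append(box.travel_span)
    return out


def expand_and_merge(
    intervals: Sequence[Interval], resp: ResponseConfig
) -> list[Interval]:
    """Morphological closing of travel intervals at scale ``d_min``.

    Each interval is dilated by ``d_min/2`` at both ends, overlapping
    dilated intervals are unioned, and the union is eroded back by
    ``d_min/2`` at its outer ends. Net effect: gaps strictly smaller than
    ``d_min`` are filled, the outer bounds of each merged run are the
    original outer bounds, and every surviving gap is >= ``d_min`` (a gap
    of exactly ``d_min`` is one the valve can just respond to, so it is
    kept).
    """
    if not intervals:
        return []
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged = [list(ivs[0])]
    # nanometer guard: a gap that is d_min up to float round-off from the
    # camera/world coordinate arithmetic still counts as servable
    for a, b in ivs[1:]:
        if a - merged[-1][1] < resp.d_min - 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """Closed-interval overlap: touching counts."""
    return a[0] <= b[1] and b[0] <= a[1]


def update_grid(
    state: LaneGridState,
    merged: Sequence[Interval],
    grid_region: Interval,
    t: float,
    v0: float,
) -> tuple[LaneGridState, list[EdgeEvent]]:
    """Advance one lane's determination for the current frame.

    Determination is 1 iff any merged interval overlaps the judgment band
    (closed intervals). A 0->1 transition emits a rising edge, 1->0 a
    falling edge, each stamped (t, v0).
    """
    active = tuple(iv for iv in merged if intervals_overlap(iv, grid_region))
    det = 1 if active else 0
    events: list[EdgeEvent] = []
    if det != state.determination:
        kind = "rising" if det == 1 else "falling"
        events.append(EdgeEvent(lane=state.lane, kind=kind, t=t, v0=v0))
    return LaneGridState(lane=state.lane, determination=det, active_intervals=active), events
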