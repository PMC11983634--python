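"""Synthetic belt scenes for the spot-spraying test bed.

Weeds are axis-aligned rectangular footprints on a conveyor belt, in a
continuous metric frame: the lane axis ``x`` runs across the direction of
travel and spans ``[0, n_lanes * lane_width]``; the travel axis ``y`` runs
along the belt, with ``y = 0`` the head of the belt (the part that reaches
the camera first).  Scenes emulate the spatial situations that stress a
per-nozzle valve controller: weeds stacked closely in one lane, weeds side
by side in adjacent lanes, compact multi-weed clusters, and overlapping
footprints, plus a ``mixed`` scenario that draws those situations at
random — the default for bench trials (50 trials of 20 weeds each).

At the tillering stage of wheat a single weed is usually at most 10 cm
across, which bounds the footprint extents drawn here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeedInstance",
    "ScenarioConfig",
    "BeltScene",
    "PlacementError",
    "generate_scene",
    "bench_trial_scenes",
    "check_scenario",
    "scene_to_csv",
    "scene_from_csv",
    "scene_to_json",
    "scene_from_json",
]

SCENARIOS = (
    "single",
    "vertical_close",
    "horizontal_close",
    "cluster",
    "overlapping",
    "mixed",
)

#: Largest weed footprint extent, meters (tillering-stage rule of thumb).
MAX_WEED_DIAMETER = 0.10
#: Smallest footprint extent drawn, meters.
MIN_WEED_EXTENT = 0.03
#: Clearance kept between weeds of different groups, meters.
GROUP_CLEARANCE = 0.02


class PlacementError(ValueError):
    """Raised when a scene cannot be laid out under its scenario constraints."""


@dataclass(frozen=True)
class WeedInstance:
    """One weed footprint on the belt (ground truth for deposition scoring).

    Spans are closed intervals in meters; ``lane_span`` is across travel,
    ``travel_span`` along it (belt frame, static).
    """

    id: int
    lane_span: tuple[float, float]
    travel_span: tuple[float, float]
    label: str = "weed"

    def __post_init__(self) -> None:
        if not (self.lane_span[1] > self.lane_span[0]):
            raise ValueError("lane_span must have positive length")
        if not (self.travel_span[1] > self.travel_span[0]):
            raise ValueError("travel_span must have positive length")

    @property
    def center(self) -> tuple[float, float]:
        return (
            0.5 * (self.lane_span[0] + self.lane_span[1]),
            0.5 * (self.travel_span[0] + self.travel_span[1]),
        )

    @property
    def travel_length(self) -> float:
        return self.travel_span[1] - self.travel_span[0]

    def intersects(self, other: "WeedInstance") -> bool:
        return _rects_intersect(self._rect, other._rect)

    @property
    def _rect(self) -> tuple[float, float, float, float]:
        return (*self.lane_span, *self.travel_span)


@dataclass(frozen=True)
class ScenarioConfig:
    """Layout recipe for one scene.

    ``gap_range`` bounds the intra-group spacing (meters) used by the
    close-proximity scenarios; ``belt_width`` must equal
    ``n_lanes * lane_width`` of the matching geometry config.
    """

    scenario: str = "mixed"
    n_weeds: int = 20
    gap_range: tuple[float, float] = (0.02, 0.08)
    belt_length: float = 8.0
    belt_width: float = 2.3
    lane_width: float = 0.23
    seed: int = 0
    max_weed_diameter: float = MAX_WEED_DIAMETER

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_weeds < 1:
            raise ValueError("n_weeds must be >= 1")
        if not (0 <= self.gap_range[0] <= self.gap_range[1]):
            raise ValueError("gap_range must be a nonnegative interval")
        n = self.belt_width / self.lane_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("belt_width must be an integer multiple of lane_width")

    @property
    def n_lanes(self) -> int:
        return int(round(self.belt_width / self.lane_width))


@dataclass(frozen=True)
class BeltScene:
    """A laid-out scene: weeds plus the config that produced it."""

    weeds: tuple[WeedInstance, ...]
    config: ScenarioConfig

    def __post_init__(self) -> None:
        for w in self.weeds:
            if w.lane_span[0] < -1e-9 or w.lane_span[1] > self.config.belt_width + 1e-9:
                raise ValueError(f"weed {w.id} outside belt width")
            if w.travel_span[0] < -1e-9 or w.travel_span[1] > self.config.belt_length + 1e-9:
                raise ValueError(f"weed {w.id} outside belt length")


# ---------------------------------------------------------------------------
# internal geometry helpers (rect = (x0, x1, y0, y1))


def _rects_intersect(a: Sequence[float], b: Sequence[float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1] and a[2] <= b[3] and b[2] <= a[3]


def _rects_clear(a: Sequence[float], b: Sequence[float], clearance: float) -> bool:
    grown = (a[0] - clearance, a[1] + clearance, a[2] - clearance, a[3] + clearance)
    return not _rects_intersect(grown, b)


def _draw_extent(rng: np.random.Generator, max_diam: float) -> float:
    return float(rng.uniform(MIN_WEED_EXTENT, max_diam))


def _lane_center(lane: int, lane_width: float) -> float:
    return (lane + 0.5) * lane_width


# ---------------------------------------------------------------------------
# group builders: each returns a list of rects positioned near the origin;
# the caller translates the group to an anchor and bounds-checks it.


def _group_single(rng, cfg: ScenarioConfig) -> list[tuple[float, float, float, float]]:
    wx = _draw_extent(rng, cfg.max_weed_diameter)
    wy = _draw_extent(rng, cfg.max_weed_diameter)
    return [(0.0, wx, 0.0, wy)]


def _group_vertical_close(rng, cfg: ScenarioConfig, n: int) -> list:
    """n weeds stacked in one lane, travel gaps drawn from gap_range."""
    lane = int(rng.integers(cfg.n_lanes))
    cx = _lane_center(lane, cfg.lane_width)
    rects = []
    y = 0.0
    for _ in range(n):
        wx = min(_draw_extent(rng, cfg.max_weed_diameter), cfg.lane_width)
        wy = _draw_extent(rng, cfg.max_weed_diameter)
        rects.append((cx - wx / 2, cx + wx / 2, y, y + wy))
        y += wy + float(rng.uniform(*cfg.gap_range))
    return rects


def _group_horizontal_close(rng, cfg: ScenarioConfig, n: int) -> list:
    """n weeds in consecutive lanes at matched travel positions."""
    if n > cfg.n_lanes:
        raise PlacementError(
            f"horizontal_close needs one lane per weed: {n} weeds > {cfg.n_lanes} lanes"
        )
    lane0 = int(rng.integers(cfg.n_lanes - n + 1))
    wy = _draw_extent(rng, cfg.max_weed_diameter)
    rects = []
    for i in range(n):
        cx = _lane_center(lane0 + i, cfg.lane_width)
        wx = min(_draw_extent(rng, cfg.max_weed_diameter), cfg.lane_width)
        rects.append((cx - wx / 2, cx + wx / 2, 0.0, wy))
    return rects


def _group_cluster(rng, cfg: ScenarioConfig, n: int) -> list:
    """A compact patch: weeds tiled over two adjacent lane columns."""
    lane0 = int(rng.integers(max(1, cfg.n_lanes - 1)))
    rects = []
    col_y = [0.0, 0.0]
    for i in range(n):
        col = i % 2
        cx = _lane_center(lane0 + col, cfg.lane_width)
        wx = min(_draw_extent(rng, cfg.max_weed_diameter), cfg.lane_width)
        wy = _draw_extent(rng, cfg.max_weed_diameter)
        y = col_y[col]
        rects.append((cx - wx / 2, cx + wx / 2, y, y + wy))
        col_y[col] = y + wy + float(rng.uniform(*cfg.gap_range))
    return rects


def _group_overlapping(rng, cfg: ScenarioConfig, n: int) -> list:
    """A chain of footprints, each intersecting the previous one."""
    rects = []
    x0, y0 = 0.0, 0.0
    for _ in range(n):
        wx = _draw_extent(rng, cfg.max_weed_diameter)
        wy = _draw_extent(rng, cfg.max_weed_diameter)
        rects.append((x0, x0 + wx, y0, y0 + wy))
        # next footprint starts inside the current one -> guaranteed overlap
        x0 += float(rng.uniform(0.2, 0.7)) * wx
        y0 += float(rng.uniform(0.2, 0.7)) * wy
    return rects


_GROUP_SIZES = {
    "single": 1,
    "vertical_close": 2,
    "horizontal_close": 2,
    "cluster": 3,
    "overlapping": 2,
}


def _build_group(rng, cfg: ScenarioConfig, kind: str, n: int) -> list:
    if kind == "single":
        return _group_single(rng, cfg)
    if kind == "vertical_close":
        return _group_vertical_close(rng, cfg, n)
    if kind == "horizontal_close":
        return _group_horizontal_close(rng, cfg, n)
    if kind == "cluster":
        return _group_cluster(rng, cfg, n)
    if kind == "overlapping":
        return _group_overlapping(rng, cfg, n)
    raise ValueError(kind)


def _place_group(
    rng,
    cfg: ScenarioConfig,
    group: list,
    placed: list,
    kind: str,
    max_attempts: int = 400,
) -> list:
    """Translate a group to a random anchor, keeping clear of prior groups.

    Horizontal/vertical/cluster groups are lane-locked across travel: only
    their travel anchor is randomized.  Returns the translated rects.
    """
    gx0 = min(r[0] for r in group)
    gx1 = max(r[1] for r in group)
    gy0 = min(r[2] for r in group)
    gy1 = max(r[3] for r in group)
    lane_locked = kind in ("vertical_close", "horizontal_close", "cluster")
    x_slack = cfg.belt_width - (gx1 - gx0)
    y_slack = cfg.belt_length - (gy1 - gy0)
    if x_slack < -1e-9 or y_slack < -1e-9:
        raise PlacementError(
            f"belt too small for a {kind!r} group of extent "
            f"{gx1 - gx0:.3f} x {gy1 - gy0:.3f} m "
            f"(belt {cfg.belt_width} x {cfg.belt_length} m)"
        )
    for _ in range(max_attempts):
        dx = 0.0 if lane_locked else float(rng.uniform(0, x_slack)) - gx0
        dy = float(rng.uniform(0, y_slack)) - gy0
        moved = [(r[0] + dx, r[1] + dx, r[2] + dy, r[3] + dy) for r in group]
        if all(
            _rects_clear(m, p, GROUP_CLEARANCE) for m in moved for p in placed
        ):
            return moved
    raise PlacementError(
        f"could not place a {kind!r} group after {max_attempts} attempts: "
        f"belt of {cfg.belt_length} m is too crowded for {cfg.n_weeds} weeds "
        f"with inter-group clearance {GROUP_CLEARANCE} m"
    )


def _partition_mixed(rng, n_weeds: int) -> list[tuple[str, int]]:
    kinds = list(_GROUP_SIZES)
    groups: list[tuple[str, int]] = []
    left = n_weeds
    while left > 0:
        kind = kinds[int(rng.integers(len(kinds)))]
        size = min(_GROUP_SIZES[kind], left)
        if size < _GROUP_SIZES[kind]:
            kind = "single" if size == 1 else kind
        groups.append((kind, size))
        left -= size
    return groups


def generate_scene(config: ScenarioConfig) -> BeltScene:
    """Lay out a scene deterministically from ``config.seed``.

    Raises :class:`PlacementError` (naming the violated constraint) when the
    belt cannot host ``n_weeds`` under the scenario's spacing rules.
    """
    rng = np.random.default_rng(config.seed)
    if config.scenario == "mixed":
        plan = _partition_mixed(rng, config.n_weeds)
    elif config.scenario == "single":
        plan = [("single", 1)] * config.n_weeds
    else:
        # one group containing every weed
        plan = [(config.scenario, config.n_weeds)]

    placed: list = []
    weeds: list[WeedInstance] = []
    next_id = 0
    for kind, size in plan:
        group = _build_group(rng, config, kind, size)
        moved = _place_group(rng, config, group, placed, kind)
        placed.extend(moved)
        for rect in moved:
            weeds.append(
                WeedInstance(
                    id=next_id,
                    lane_span=(rect[0], rect[1]),
                    travel_span=(rect[2], rect[3]),
                    label=kind,
                )
            )
            next_id += 1
    return BeltScene(weeds=tuple(weeds), config=config)


def bench_trial_scenes(
    n_trials: int,
    n_weeds: int = 20,
    seed: int = 0,
    scenario: str = "mixed",
    **config_kwargs,
) -> list[BeltScene]:
    """Scenes for a bench campaign: ``n_trials`` mixed scenes of ``n_weeds``.

    Per-trial seeds are split deterministically from the master seed, so the
    full campaign is reproducible from one integer.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    master = np.random.SeedSequence(seed)
    scenes = []
    for child in master.spawn(n_trials):
        trial_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        cfg = ScenarioConfig(
            scenario=scenario, n_weeds=n_weeds, seed=trial_seed, **config_kwargs
        )
        scenes.append(generate_scene(cfg))
    return scenes


# ---------------------------------------------------------------------------
# scenario predicates (each generated scene must pass its own predicate)


def _lane_of(w: WeedInstance, cfg: ScenarioConfig) -> int:
    return int(w.center[0] // cfg.lane_width)


def check_scenario(scene: BeltScene) -> bool:
    """True iff the scene satisfies its declared scenario's constraints."""
    cfg = scene.config
    ws = scene.weeds
    kind = cfg.scenario
    if len(ws) != cfg.n_weeds:
        return False
    if kind in ("single", "vertical_close", "horizontal_close", "cluster"):
        if any(a.intersects(b) for i, a in enumerate(ws) for b in ws[i + 1 :]):
            return False
    if kind == "single" or len(ws) < 2:
        return True
    if kind == "vertical_close":
        if len({_lane_of(w, cfg) for w in ws}) != 1:
            return False
        ys = sorted(w.travel_span for w in ws)
        gaps = [b[0] - a[1] for a, b in zip(ys, ys[1:])]
        tol = 1e-9
        return all(cfg.gap_range[0] - tol <= g <= cfg.gap_range[1] + tol for g in gaps)
    if kind == "horizontal_close":
        lanes = sorted(_lane_of(w, cfg) for w in ws)
        if lanes != list(range(lanes[0], lanes[0] + len(ws))):
            return False
        spans = [w.travel_span for w in ws]
        return all(s == spans[0] for s in spans[1:])
    if kind == "cluster":
        hull_y = max(w.travel_span[1] for w in ws) - min(w.travel_span[0] for w in ws)
        n_rows = (len(ws) + 1) // 2
        max_hull = n_rows * MAX_WEED_DIAMETER + (n_rows - 1) * cfg.gap_range[1] + 1e-9
        lanes = {_lane_of(w, cfg) for w in ws}
        return hull_y <= max_hull and max(lanes) - min(lanes) <= 1
    if kind == "overlapping":
        ordered = sorted(ws, key=lambda w: w.travel_span[0])
        return all(a.intersects(b) for a, b in zip(ordered, ordered[1:]))
    if kind == "mixed":
        return True
    return False


# ---------------------------------------------------------------------------
# persistence: CSV (weeds only) and JSON (weeds + config)


def scene_to_csv(scene: BeltScene, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [w.id for w in scene.weeds],
            "label": [w.label for w in scene.weeds],
            "x_min": [round(w.lane_span[0], 6) for w in scene.weeds],
            "x_max": [round(w.lane_span[1], 6) for w in scene.weeds],
            "y_min": [round(w.travel_span[0], 6) for w in scene.weeds],
            "y_max": [round(w.travel_span[1], 6) for w in scene.weeds],
        }
    )
    df.to_csv(path, index=False)


def scene_from_csv(path: str | Path, config: ScenarioConfig) -> BeltScene:
    df = pd.read_csv(path)
    weeds = tuple(
        WeedInstance(
            id=int(r.id),
            lane_span=(float(r.x_min), float(r.x_max)),
            travel_span=(float(r.y_min), float(r.y_max)),
            label=str(r.label),
        )
        for r in df.itertuples()
    )
    return BeltScene(weeds=weeds, config=config)


def scene_to_json(scene: BeltScene, path: str | Path) -> None:
    payload = {
        "config": {
            "scenario": scene.config.scenario,
            "n_weeds": scene.config.n_weeds,
            "gap_range": list(scene.config.gap_range),
            "belt_length": scene.config.belt_length,
            "belt_width": scene.config.belt_width,
            "lane_width": scene.config.lane_width,
            "seed": scene.config.seed,
            "max_weed_diameter": scene.config.max_weed_diameter,
        },
        "weeds": [
            {
                "id": w.id,
                "label": w.label,
                "lane_span": list(w.lane_span),
                "travel_span": list(w.travel_span),
            }
            for w in scene.weeds
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def scene_from_json(path: str | Path) -> BeltScene:
    payload = json.loads(Path(path).read_text())
    c = payload["config"]
    cfg = ScenarioConfig(
        scenario=c["scenario"],
        n_weeds=c["n_weeds"],
        gap_range=tuple(c["gap_range"]),
        belt_length=c["belt_length"],
        belt_width=c["belt_width"],
        lane_width=c["lane_width"],
        seed=c["seed"],
        max_weed_diameter=c["max_weed_diameter"],
    )
    weeds = tuple(
        WeedInstance(
            id=w["id"],
            lane_span=tuple(w["lane_span"]),
            travel_span=tuple(w["travel_span"]),
            label=w["label"],
        )
        for w in payload["weeds"]
    )
    return BeltScene(weeds=weeds, config=cfg)
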