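"""Per-frame detection boxes for a moving scene.

The real system runs a lightweight object detector on 60 fps camera
frames; here detection is abstracted behind three sources with one output
type:

* :func:`oracle_detect` — exact ground-truth boxes, clipped to the camera
  view: a pure function of (scene, time, view window).
* :func:`perturb_detections` — seeded misses and edge jitter on top of any
  frame, to emulate an imperfect detector.
* :func:`read_jsonl` / :func:`write_jsonl` — a hook for an external
  detector's box stream (one JSON record per frame, world coordinates;
  pixel-to-world conversion is the caller's duty).

World frame: the travel axis advances with the belt toward the nozzles;
the camera view is a fixed travel-axis window. A weed placed at belt
coordinate ``y`` sits at world coordinate ``s(t) - y`` once the belt has
advanced ``s(t)`` meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from spotspray.scene_gen import BeltScene

__all__ = [
    "DetectionBox",
    "FrameDetections",
    "NoiseParams",
    "oracle_detect",
    "perturb_detections",
    "write_jsonl",
    "read_jsonl",
]


@dataclass(frozen=True)
class DetectionBox:
    """One predicted box, world coordinates (meters), confidence in [0, 1]."""

    lane_span: tuple[float, float]
    travel_span: tuple[float, float]
    confidence: float = 1.0
    source_weed_id: int | None = None

    def __post_init__(self) -> None:
        if not (self.lane_span[1] > self.lane_span[0]):
            raise ValueError("lane_span must have positive length")
        if not (self.travel_span[1] > self.travel_span[0]):
            raise ValueError("travel_span must have positive length")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class FrameDetections:
    """Boxes visible at time ``t``; ``view_window`` is the camera's current
    travel-axis extent in world coordinates. Boxes are clipped to it."""

    t: float
    boxes: tuple[DetectionBox, ...]
    view_window: tuple[float, float]


@dataclass(frozen=True)
class NoiseParams:
    """Detector imperfection model.

    ``miss_mode`` selects what a miss means: ``"per_box"`` drops each box
    independently every frame (the raw perturbation contract);
    ``"per_weed"`` suppresses all boxes of an unlucky weed for an entire
    trial, which is what a bench recognition rate below 100% corresponds
    to — a per-frame drop would almost never hide a weed that stays in
    view for dozens of frames.
    """

    miss_prob: float = 0.0
    jitter_sd: float = 0.0
    confidence_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    miss_mode: str = "per_box"

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob < 1.0):
            raise ValueError("miss_prob must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.miss_mode not in ("per_box", "per_weed"):
            raise ValueError("miss_mode must be 'per_box' or 'per_weed'")


def oracle_detect(
    scene: BeltScene,
    t: float,
    view_window: tuple[float, float],
    belt_travel: float | None = None,
) -> FrameDetections:
    """Ground-truth boxes for every weed intersecting the view at time ``t``.

    ``belt_travel`` is the belt advance s(t) in meters; if omitted it is
    taken as ``t`` times 1 m/s (useful for static tests). Each returned box
    equals the weed's true bounding box mapped to world coordinates and
    clipped to ``view_window``, confidence 1.0.
    """
    s = t if belt_travel is None else belt_travel
    lo, hi = view_window
    boxes = []
    for w in scene.weeds:
        y0 = s - w.travel_span[1]
        y1 = s - w.travel_span[0]
        cy0, cy1 = max(y0, lo), min(y1, hi)
        if cy1 <= cy0:  # outside (or degenerate sliver at) the window
            continue
        boxes.append(
            DetectionBox(
                lane_span=w.lane_span,
                travel_span=(cy0, cy1),
                confidence=1.0,
                source_weed_id=w.id,
            )
        )
    return FrameDetections(t=t, boxes=tuple(boxes), view_window=view_window)


def perturb_detections(frame: FrameDetections, params: NoiseParams) -> FrameDetections:
    """Seeded noise on one frame: per-box drops, edge jitter, confidence draw.

    Deterministic given ``(params.seed, frame.t)``; the frame time is folded
    into the stream seed so successive frames get independent draws.
    """
    if params.miss_prob == 0 and params.jitter_sd == 0 and params.confidence_range == (1.0, 1.0):
        return frame
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, int(round(frame.t * 1e6)) & 0x7FFFFFFF])
    )
    lo, hi = frame.view_window
    kept = []
    for box in frame.boxes:
        if params.miss_prob > 0 and rng.random() < params.miss_prob:
            continue
        x0, x1 = box.lane_span
        y0, y1 = box.travel_span
        if params.jitter_sd > 0:
            x0, x1, y0, y1 = (
                np.array([x0, x1, y0, y1]) + rng.normal(0.0, params.jitter_sd, 4)
            ).tolist()
        y0, y1 = max(y0, lo), min(y1, hi)
        if x1 <= x0 or y1 <= y0:  # jitter collapsed the box
            continue
        conf = float(rng.uniform(*params.confidence_range))
        kept.append(
            DetectionBox(
                lane_span=(x0, x1),
                travel_span=(y0, y1),
                confidence=min(max(conf, 0.0), 1.0),
                source_weed_id=box.source_weed_id,
            )
        )
    return replace(frame, boxes=tuple(kept))


def missed_weed_ids(scene: BeltScene, params: NoiseParams) -> frozenset[int]:
    """Weed ids suppressed for a whole trial under ``miss_mode='per_weed'``.

    One Bernoulli(miss_prob) draw per weed, seeded by ``params.seed`` only,
    so the same scene and params always hide the same weeds.
    """
    if params.miss_mode != "per_weed" or params.miss_prob == 0:
        return frozenset()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    draws = rng.random(len(scene.weeds))
    return frozenset(
        w.id for w, u in zip(scene.weeds, draws) if u < params.miss_prob
    )


# ---------------------------------------------------------------------------
# external-detector hook: JSONL, one frame per line


def write_jsonl(frames: Iterable[FrameDetections], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            rec = {
                "t": fr.t,
                "view_window": list(fr.view_window),
                "boxes": [
                    {
                        "x_min": b.lane_span[0],
                        "x_max": b.lane_span[1],
                        "y_min": b.travel_span[0],
                        "y_max": b.travel_span[1],
                        "conf": b.confidence,
                    }
                    for b in fr.boxes
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path: str | Path) -> Iterator[FrameDetections]:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            yield FrameDetections(
                t=float(rec["t"]),
                view_window=tuple(rec["view_window"]),
                boxes=tuple(
                    DetectionBox(
                        lane_span=(b["x_min"], b["x_max"]),
                        travel_span=(b["y_min"], b["y_max"]),
                        confidence=b.get("conf", 1.0),
                    )
                    for b in rec["boxes"]
                ),
            )
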