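"""Closed-loop emulation of the spot-spraying test bed.

A conveyor belt carries a synthetic scene toward a fixed camera/nozzle
bar at a randomly varying speed inside a set interval. Every camera
frame (60 fps) runs detection -> lane assignment -> cluster merging ->
grid determination; every feedback tick (10 Hz) the controller
integrates speed and fires ripe valve commands; a fired command puts the
valve into its new state t1 + t2 later and liquid follows t3 after that,
so the full command-to-ground latency is t_c = t1 + t2 + t3. Liquid on
the moving belt leaves wetted travel-axis intervals per nozzle — the
virtual water-sensitive paper read out by :func:`score_deposition`.

The belt's true position is the exact integral of the piecewise-constant
speed profile; the controller only ever sees the discrete 10 Hz samples.
That gap between truth and the controller's trapezoidal estimate is the
phenomenon under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from spotspray.scene_gen import BeltScene
from spotspray.detection import (
    FrameDetections,
    NoiseParams,
    missed_weed_ids,
    oracle_detect,
    perturb_detections,
)
from spotspray.spray_decision import (
    EdgeEvent,
    GeometryConfig,
    LaneGridState,
    ResponseConfig,
    assign_lanes,
    expand_and_merge,
    intervals_overlap,
    update_grid,
)
from spotspray.hysteresis import (
    DelayConfig,
    HysteresisController,
    SpeedSample,
    ValveCommand,
    delay_time,
)

__all__ = [
    "SimConfig",
    "SpeedProfile",
    "DepositionRecord",
    "SimulationLog",
    "make_speed_profile",
    "run_trial",
    "run_bench",
    "score_deposition",
]

Interval = tuple[float, float]

#: Margin of the virtual water-sensitive paper card beyond the weed patch,
#: meters per side. The card is local to its weed: a burst aimed at a
#: close neighbor marks this weed's card only where it actually reaches
#: the card, which keeps per-weed targeting readouts meaningful inside
#: merged clusters.
PAPER_MARGIN = 0.045


@dataclass(frozen=True)
class SimConfig:
    """Everything one trial needs besides the scene itself."""

    speed_interval: tuple[float, float] = (0.3, 0.4)
    frame_rate: float = 60.0
    speed_feedback_rate: float = 10.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    delays: DelayConfig = field(default_factory=DelayConfig)
    footprint_len: float = 0.02
    n_weeds: int = 20
    seed: int = 0
    #: speed law: "random_walk" (bounded walk at feedback ticks) or "constant"
    speed_law: str = "random_walk"
    #: largest per-tick speed change of the random walk, m/s
    walk_step: float = 0.02
    #: optional Gaussian noise on the samples the controller sees, m/s
    feedback_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        v_lo, v_hi = self.speed_interval
        if not (0 < v_lo <= v_hi):
            raise ValueError("need 0 < v_lo <= v_hi")
        if self.frame_rate <= 0 or self.speed_feedback_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.speed_law not in ("random_walk", "constant"):
            raise ValueError("speed_law must be 'random_walk' or 'constant'")

    @property
    def h(self) -> float:
        return 1.0 / self.speed_feedback_rate


@dataclass(frozen=True)
class SpeedProfile:
    """Piecewise-constant true speed: value ``v[k]`` holds on
    [tick_t[k], tick_t[k+1]). Distance is integrated exactly."""

    tick_t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "_s", np.concatenate(
            ([0.0], np.cumsum(self.v[:-1] * np.diff(self.tick_t)))
        ))

    def value(self, t: float) -> float:
        k = min(int(np.searchsorted(self.tick_t, t, side="right")) - 1, len(self.v) - 1)
        return float(self.v[max(k, 0)])

    def distance(self, t: float) -> float:
        """Exact belt travel s(t) from t=0."""
        k = min(int(np.searchsorted(self.tick_t, t, side="right")) - 1, len(self.v) - 1)
        k = max(k, 0)
        return float(self._s[k] + self.v[k] * (t - self.tick_t[k]))


def make_speed_profile(cfg: SimConfig, duration: float) -> SpeedProfile:
    """Bounded random walk inside ``speed_interval`` at the feedback rate.

    ``speed_law='constant'`` (or a degenerate interval) pins the speed to
    the interval midpoint. Deterministic given ``cfg.seed``.
    """
    h = cfg.h
    n = int(math.ceil(duration / h)) + 1
    ticks = np.arange(n) * h
    v_lo, v_hi = cfg.speed_interval
    if cfg.speed_law == "constant" or v_lo == v_hi:
        return SpeedProfile(tick_t=ticks, v=np.full(n, 0.5 * (v_lo + v_hi)))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5F33D]))
    v = np.empty(n)
    v[0] = rng.uniform(v_lo, v_hi)
    steps = rng.uniform(-cfg.walk_step, cfg.walk_step, n - 1)
    for k in range(1, n):
        v[k] = min(max(v[k - 1] + steps[k - 1], v_lo), v_hi)
    return SpeedProfile(tick_t=ticks, v=v)


@dataclass
class DepositionRecord:
    """Wetted ground intervals per nozzle, belt coordinates (the virtual
    water-sensitive paper). Intervals are merged, hence disjoint."""

    wetted: dict[int, list[Interval]]

    def lanes_wetting(self, lane_indices: Sequence[int]) -> list[Interval]:
        out: list[Interval] = []
        for i in lane_indices:
            out.extend(self.wetted.get(i, []))
        return out


@dataclass
class SimulationLog:
    scene: BeltScene
    config: SimConfig
    profile: SpeedProfile
    samples: list[SpeedSample]
    edges: list[EdgeEvent]
    commands: list[ValveCommand]
    valve_windows: dict[int, list[Interval]]  # (t_on, t_off) of liquid per nozzle
    deposition: DepositionRecord
    detected_ids: frozenset[int]
    duration: float


def _lanes_of_span(span: Interval, geom: GeometryConfig) -> list[int]:
    first = max(0, int(math.floor(span[0] / geom.lane_width)))
    last = min(geom.n_lanes - 1, int(math.floor(span[1] / geom.lane_width)))
    if first > 0 and span[0] == first * geom.lane_width:
        first -= 1
    return list(range(first, last + 1))


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def run_trial(
    scene: BeltScene,
    cfg: SimConfig,
    detector: Callable[..., FrameDetections] | None = None,
    noise: NoiseParams | None = None,
) -> SimulationLog:
    """Run one bench trial end to end.

    ``detector(scene, t, view_window, belt_travel)`` defaults to the exact
    oracle; ``noise`` perturbs its output. Raises ``ValueError`` before
    running if the configuration cannot work (e.g. in lead mode the
    compensated distance would go negative at the top speed: the judgment
    band sits too close to the nozzles for the delays).
    """
    geom, resp, delays = cfg.geometry, cfg.response, cfg.delays
    if abs(scene.config.belt_width - geom.width) > 1e-6:
        raise ValueError("scene belt_width does not match geometry n_lanes * lane_width")
    t_c = delay_time(delays)
    v_hi = cfg.speed_interval[1]
    if delays.comp_mode == "lead" and geom.L1 - delays.L3 < v_hi * t_c:
        raise ValueError(
            f"lead compensation infeasible: L1 - L3 = {geom.L1 - delays.L3:.3f} m "
            f"is less than travel v_hi * t_c = {v_hi * t_c:.3f} m during the delays"
        )

    belt_length = scene.config.belt_length
    s_end = belt_length + geom.nozzle_y + 2.0 * (geom.L1 + delays.L3 + 0.5)
    duration = s_end / cfg.speed_interval[0] + 10.0
    profile = make_speed_profile(cfg, duration)

    # master clock: frames and feedback ticks expressed in integer counts
    ratio = cfg.frame_rate / cfg.speed_feedback_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("frame_rate must be an integer multiple of speed_feedback_rate")
    fb_every = int(round(ratio))
    dt = 1.0 / cfg.frame_rate

    detector = detector or oracle_detect
    missed = missed_weed_ids(scene, noise) if noise is not None else frozenset()
    if missed:
        visible = replace(
            scene, weeds=tuple(w for w in scene.weeds if w.id not in missed)
        )
    else:
        visible = scene
    frame_noise = None
    if noise is not None and noise.miss_mode == "per_box":
        frame_noise = noise
    elif noise is not None and (noise.jitter_sd > 0 or noise.confidence_range != (1.0, 1.0)):
        frame_noise = replace(noise, miss_prob=0.0, miss_mode="per_box")

    controller = HysteresisController(
        n_nozzles=geom.n_lanes, delays=delays, L1=geom.L1, h=cfg.h
    )
    fb_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xFB]))
    states = [LaneGridState(lane=i) for i in range(geom.n_lanes)]
    view = (0.0, geom.view_len)
    grid_region = geom.grid_region

    samples: list[SpeedSample] = []
    edges: list[EdgeEvent] = []
    commands: list[ValveCommand] = []
    detected: set[int] = set()
    held_v = profile.v[0]  # latest feedback sample value the controller saw

    k = 0
    max_k = int(duration / dt)
    while k <= max_k:
        t = k * dt
        s = profile.distance(t)
        if k % fb_every == 0:
            v_meas = profile.value(t)
            if cfg.feedback_noise_sd > 0:
                v_meas = max(0.0, v_meas + fb_rng.normal(0.0, cfg.feedback_noise_sd))
            held_v = v_meas
            sample = SpeedSample(t=t, v=v_meas)
            samples.append(sample)
            commands.extend(controller.on_sample(sample))
        # frame: detection -> decision
        frame = detector(visible, t, view, belt_travel=s)
        if frame_noise is not None:
            frame = perturb_detections(frame, frame_noise)
        per_lane = assign_lanes(frame.boxes, geom)
        for box in frame.boxes:
            if box.source_weed_id is not None:
                detected.add(box.source_weed_id)
        for lane in range(geom.n_lanes):
            merged = expand_and_merge(per_lane[lane], resp)
            states[lane], evs = update_grid(states[lane], merged, grid_region, t, held_v)
            for ev in evs:
                edges.append(ev)
                controller.on_edge(ev.lane, ev.kind, ev.t, ev.v0)
        if s >= s_end and controller.pending == 0:
            break
        k += 1
    t_last = k * dt

    # physical actuation: liquid on/off t_c after each command; force-close
    # any open left dangling at the end of the trial
    valve_windows: dict[int, list[Interval]] = {i: [] for i in range(geom.n_lanes)}
    open_t: dict[int, float | None] = {i: None for i in range(geom.n_lanes)}
    for cmd in commands:
        if cmd.action == "open":
            open_t[cmd.nozzle] = cmd.t + t_c
        else:
            t_on = open_t[cmd.nozzle]
            if t_on is not None:
                valve_windows[cmd.nozzle].append((t_on, cmd.t + t_c))
                open_t[cmd.nozzle] = None
    for nozzle, t_on in open_t.items():
        if t_on is not None:
            valve_windows[nozzle].append((t_on, t_last + t_c))

    nozzle_y = geom.nozzle_y
    half_fp = cfg.footprint_len / 2.0
    wetted: dict[int, list[Interval]] = {}
    for nozzle, windows in valve_windows.items():
        ivs = []
        for t_on, t_off in windows:
            a = profile.distance(t_on) - nozzle_y - half_fp
            b = profile.distance(t_off) - nozzle_y + half_fp
            a, b = max(a, 0.0), min(b, belt_length)
            if b > a:
                ivs.append((a, b))
        wetted[nozzle] = _merge_intervals(ivs)

    return SimulationLog(
        scene=scene,
        config=cfg,
        profile=profile,
        samples=samples,
        edges=edges,
        commands=commands,
        valve_windows=valve_windows,
        deposition=DepositionRecord(wetted=wetted),
        detected_ids=frozenset(detected),
        duration=t_last,
    )


def score_deposition(
    scene: BeltScene,
    deposition: DepositionRecord,
    geom: GeometryConfig,
    paper_margin: float = PAPER_MARGIN,
) -> dict[int, dict]:
    """Read the virtual water-sensitive paper for every weed.

    A weed counts as sprayed iff some wetted interval in a lane its
    footprint overlaps also overlaps its travel span (closed intervals:
    touching counts). Its paper card spans the weed's travel extent plus
    ``paper_margin`` per side; the discoloration is the hull of the
    wetted intervals clipped to the card. The card is deliberately local:
    inside a merged cluster one continuous burst wets several weeds, and
    each weed's readout must reflect the liquid near *that* weed, not the
    midpoint of the whole burst.

    Returns ``{weed_id: {"sprayed", "discoloration_span",
    "discoloration_center", "offset"}}`` with offset = discoloration
    center minus weed travel center (meters, None if dry).
    """
    out: dict[int, dict] = {}
    for w in scene.weeds:
        lanes = _lanes_of_span(w.lane_span, geom)
        wet = deposition.lanes_wetting(lanes)
        sprayed = any(intervals_overlap(iv, w.travel_span) for iv in wet)
        cy = w.center[1]
        card = (w.travel_span[0] - paper_margin, w.travel_span[1] + paper_margin)
        local = [
            (max(a, card[0]), min(b, card[1]))
            for a, b in wet
            if intervals_overlap((a, b), card)
        ]
        local = [(a, b) for a, b in local if b > a]
        if local:
            span = (min(a for a, _ in local), max(b for _, b in local))
            center = 0.5 * (span[0] + span[1])
            offset = center - cy
        else:
            span = center = offset = None
        out[w.id] = {
            "sprayed": sprayed,
            "discoloration_span": span,
            "discoloration_center": center,
            "offset": offset,
        }
    return out


def run_bench(
    speed_intervals: Sequence[tuple[float, float]] = ((0.3, 0.4), (0.4, 0.5), (0.5, 0.6)),
    n_trials: int = 50,
    n_weeds: int = 20,
    seed: int = 0,
    base_cfg: SimConfig | None = None,
    noise: NoiseParams | None = None,
    coverage_mode: str = "overlap",
):
    """A full bench campaign: ``n_trials`` trials of ``n_weeds`` weeds for
    every speed interval, with pooled counts per interval.

    Per-trial scene, simulation and noise seeds are all split from the one
    master ``seed``. Returns ``(spray_counts, coverage_rows, outcomes)``
    where ``spray_counts`` maps a speed-range label to
    (n_total, n_detected, n_wetted_detected), ``coverage_rows`` maps it to
    (mean coverage fraction, offsets in meters), and ``outcomes`` holds the
    per-weed score dicts, keyed (label, trial index).
    """
    from spotspray.scene_gen import bench_trial_scenes
    from spotspray import metrics as _metrics

    base_cfg = base_cfg or SimConfig()
    spray_counts: dict[str, tuple[int, int, int]] = {}
    coverage_rows: dict[str, tuple[float, list[float]]] = {}
    outcomes: dict[tuple[str, int], dict] = {}
    for idx, (v_lo, v_hi) in enumerate(speed_intervals):
        label = f"{v_lo:g}~{v_hi:g}"
        interval_seed = (seed * 1000003 + idx) & 0x7FFFFFFF
        scenes = bench_trial_scenes(
            n_trials,
            n_weeds,
            seed=interval_seed,
            belt_width=base_cfg.geometry.width,
            lane_width=base_cfg.geometry.lane_width,
        )
        n_total = n_det = n_wet = 0
        offsets: list[float] = []
        covers: list[float] = []
        for i, scene in enumerate(scenes):
            trial_seed = (interval_seed * 7919 + i) & 0x7FFFFFFF
            cfg = replace(
                base_cfg, speed_interval=(v_lo, v_hi), n_weeds=n_weeds, seed=trial_seed
            )
            trial_noise = replace(noise, seed=trial_seed) if noise is not None else None
            log = run_trial(scene, cfg, noise=trial_noise)
            scored = score_deposition(scene, log.deposition, cfg.geometry)
            outcomes[(label, i)] = scored
            n_total += len(scene.weeds)
            n_det += len(log.detected_ids)
            for w in scene.weeds:
                rec = scored[w.id]
                if w.id in log.detected_ids and rec["sprayed"]:
                    n_wet += 1
                    covers.append(
                        _metrics.coverage_rate(
                            w.travel_span, rec["discoloration_span"], coverage_mode
                        )
                    )
                    if rec["offset"] is not None:
                        offsets.append(rec["offset"])
        spray_counts[label] = (n_total, n_det, n_wet)
        mean_cov = float(np.mean(covers)) if covers else 0.0
        coverage_rows[label] = (mean_cov, offsets)
    return spray_counts, coverage_rows, outcomes
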