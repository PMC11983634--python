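# Methods

## The control problem

A spot sprayer opens individual nozzles only over detected weeds. Three
physical facts make this nontrivial:

1. **Geometry.** The camera sees the weed a distance `L1` before it
   reaches the nozzle line, so every decision is about the future.
2. **Latency.** Between a command and liquid on the ground lie equipment
   processing (`t1`), solenoid-valve response (`t2`) and droplet
   settling (`t3`); during `t_c = t1 + t2 + t3` the target keeps moving.
3. **Discreteness.** Ground speed arrives as samples at 10 Hz, and the
   valve has a finite open/close cycling rate, so two weeds closer than
   `d_min = v_nominal / f_valve` along travel cannot receive separate
   bursts.

`spotspray` models the full loop: scene → per-frame detection boxes →
per-nozzle lane decision → distance-triggered valve scheduling →
delayed actuation → deposition scoring.

## Coordinate frames and the event loop

All positions are metric and continuous. The **world frame** is fixed to
the nozzle bar: the lane axis spans `[0, n_lanes · lane_width]`, the
travel axis points with belt motion, the camera view occupies the fixed
window `[0, view_len]`, the judgment band `[grid_y, grid_y+grid_depth]`
lies inside it, and the nozzle line sits `L1` past the band. The **belt
frame** is the scene's own coordinate system; a weed at belt coordinate
`y` appears at world coordinate `s(t) − y`, where `s(t)` is the exact
integral of the true speed profile.

The simulator's master clock runs at the frame rate (60 fps), with
speed-feedback ticks every sixth frame (10 Hz; the frame rate must be an
integer multiple of the feedback rate). Within a tick the feedback
sample is processed first, then the frame, so an edge detected on a
frame is stamped with the latest *causal* speed sample — a controller
cannot read a future one. Truth (belt position) is integrated exactly;
the controller only ever sees the discrete samples. That separation is
the point of the exercise.

## Decision layer

Boxes are assigned to every lane their lane-axis span overlaps (closed
intervals, so a box edge exactly on a lane seam triggers both lanes —
double-spraying a seam beats leaking, consistent with the 1.5 cm nozzle
overlap). Per lane, travel intervals are merged by a one-dimensional
morphological closing at scale `d_min`: dilate each by `d_min/2`, union,
erode the outer ends. Gaps strictly below `d_min` disappear; a gap of
exactly `d_min` is one the valve can just service and is kept (a 1 nm
guard absorbs float round-off from the frame transforms, so "exactly
`d_min`" is robust). The lane's determination value is 1 iff a merged
interval overlaps the judgment band; its transitions are the edge
events.

## Hysteresis (latency-compensation) layer

Each edge arms a spray event with target distance `A` and a private
trapezoidal accumulator `M` that restarts at zero — the per-event
integration clock of the scheme. On each 10 Hz sample every pending
event gains `(h/2)(v_prev + v_now)` against its own history (seeded with
its `v0`), and events fire in strict creation order per nozzle when
`M ≥ A`, which guarantees open/close alternation even with several
events in flight. The first increment after an edge counts a full `h`
although less time has elapsed; that bias is below `v·h` and is included
in the error budget below.

Two sign conventions for the delay term are kept:

* `as_printed`: `A = L1 + v0·t_c + L3`. The command fires *after* the
  extra delay travel, so liquid lands about `2·v·t_c + L3` past the
  weed; with the defaults this misses outright. The convention is
  modeled faithfully and flagged, not corrected.
* `lead` (default for bench runs): `A = L1 − v0·t_c ± L3`, floored at
  zero. The command leads the target by the delay travel, so after the
  real delays elapse the liquid arrives at `L1` exactly. The margin `L3`
  is applied with the sign that widens the burst — open `L3` early,
  close `L3` late. A symmetric shift cannot do a margin's job: the
  firing quantization can reach a full `v·h` (≤ 6 cm) per edge, enough
  to slide an unwidened burst entirely off a 3 cm weed.

A lead configuration with `L1 − L3 < v_hi · t_c` is rejected before the
run: no command issued at the judgment band can be early enough.

### Error budget (constant speed)

Each burst endpoint is displaced from its ideal position by at most the
10 Hz firing quantum (`< v·h`, plus the sub-sample start bias) and the
60 fps edge-detection quantum (`< v/frame_rate`). With `grid_depth` =
0.02 m and `L3` = 0.01 m the systematic terms cancel at the burst
center, leaving a center error below `v·h + v/frame_rate` — strictly
inside the `v·h + footprint_len/2` acceptance envelope for all
`v < 0.6 m/s`. This bound is deterministic, not statistical, which is
why the closed-loop suite can demand it for every one of 1000 weeds.

## Bench protocol and deposition scoring

A campaign runs 50 trials of 20 weeds per speed interval (0.3–0.4,
0.4–0.5, 0.5–0.6 m/s), the scale of the physical test bed, with mixed
scene layouts; all per-trial seeds split from one master seed. The true
speed follows a bounded random walk (step ≤ 0.02 m/s per tick, clipped
to the interval — sprayers hold speed roughly constant while spraying),
switchable to constant.

Liquid is bookkept per nozzle as wetted belt intervals: a burst from
`t_on` to `t_off` (command times plus `t_c`) wets
`[s(t_on) − nozzle_y − footprint/2, s(t_off) − nozzle_y + footprint/2]`,
with `footprint_len` = 0.02 m standing in for the spray cone's
along-travel extent. Each weed owns a virtual water-sensitive paper card
spanning its footprint plus 0.045 m per side. A weed is *sprayed* iff a
wetted interval in one of its lanes touches its travel span; its
discoloration is the hull of the wetting clipped to the card, and the
targeting offset is the discoloration center minus the weed center. The
card is deliberately local: inside a merged cluster one burst wets
several weeds, and a readout centered on the whole burst would say
nothing about where the liquid sat relative to each weed. The 0.045 m
margin is the largest for which the acceptance error bound remains
provable over the 0.3–0.6 m/s range; a wider card would let a
neighbor's wetting drag the measured center.

Rates follow the paper-card protocol: recognition = detected/total,
spraying = wetted-detected/detected, hit = their product (pooled counts
across trials, so the campaign hit rate is exactly the product of the
pooled rates). Coverage is reported in two modes: the protocol's stated
ratio weed-length/discoloration-length (`as_printed`, capped at 1 —
kept verbatim although it reads inverted) and the plausible
`overlap` mode, |discoloration ∩ weed| / |weed|, which the campaign
report uses.

## Detector model

Detection is abstracted: an exact oracle (true boxes clipped to the
view, confidence 1), a seeded perturbation (per-box misses, Gaussian
edge jitter, confidence draws), and a JSONL stream hook for an external
detector. Misses come in two semantics: `per_box` drops each box
independently every frame — the right model for frame-level noise, but a
weed in view for dozens of frames would almost never stay hidden — and
`per_weed`, which hides an unlucky weed for the whole trial and is what
a bench recognition rate below 100 % corresponds to. Bench campaigns use
`per_weed`.

## Defaults

| parameter | default | why |
|---|---|---|
| `n_lanes`, `lane_width` | 10, 0.23 m | ten nozzles; 30° fan covers 23 cm at 42 cm height |
| `view_len` | 1.0 m | along-travel camera footprint (config, not a datasheet value) |
| `grid_y`, `grid_depth` | 0.93, 0.02 m | thin judgment band near the downstream edge of the view |
| `L1` | 0.20 m | plausible band-to-nozzle distance; keeps lead mode feasible at 0.6 m/s |
| `t1, t2, t3` | 0.05, 0.06, 0.05 s | processing, valve response (< 60 ms class), settling over ~0.4 m fall |
| `L3` | 0.01 m | burst-widening margin; with `grid_depth/2` it centers the burst |
| `d_min` | 0.05 m | `v_nominal/f_valve` = 0.5 m/s ÷ 10 Hz valve cycling |
| `footprint_len` | 0.02 m | along-travel wetting of one fan at working height |
| `h` | 0.1 s | 10 Hz speed telemetry |
| `frame_rate` | 60 fps | camera frame rate |
| `walk_step` | 0.02 m/s | near-uniform travel while spraying |

## What the synthetic bench does and does not show

The generator reproduces the *spatial* stress cases (same-lane
proximity at the valve threshold, adjacent-lane coincidence, clusters,
overlap) and the *temporal* ones (latency, discrete feedback, varying
speed). It does not model image formation, detector confusion between
wheat and weeds, spray drift, pressure transients, belt vibration, or
speed-sensor bias; a passing suite therefore validates the decision and
compensation logic, not field performance. Known limitations, beyond
those: the lane seam convention can double-spray a boundary box; the
`as_printed` compensation mode is retained only to expose its behavior;
and recognition under `per_weed` misses is a modeling choice calibrated
by a single probability, not a detector benchmark.
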