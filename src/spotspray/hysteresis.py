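"""Distance-triggered valve scheduling under hardware latency.

Between the judgment band and the nozzle line lies a fixed distance L1,
and between a command and liquid on the ground lie three delays: equipment
processing t1, solenoid response t2 and droplet settling t3, summing to
t_c. When a lane's determination value flips, the controller computes an
activation distance A and arms a spray event; the sprayer's travel since
the flip is then estimated from discrete 10 Hz speed feedback with the
composite trapezoidal rule, and the event fires (emits its valve command)
as soon as the accumulated distance M reaches A.

Two sign conventions for the delay term are kept:

* ``as_printed`` — A = L1 + v0*t_c + L3: the delay travel is *added* to
  the trigger distance.
* ``lead`` — A = max(0, L1 - v0*t_c + L3): the command is issued early
  enough that, after the real delays elapse, liquid arrives exactly at
  L1. A command issued later than the target can never cancel a
  downstream delay, so this is the mode under which the closed-loop
  simulator hits its targets; both are provided and the discrepancy is
  flagged rather than silently corrected.

Pending events live in per-nozzle FIFO queues (at most one of open/close
can be armed per determination flip, but fast belts and slow valves can
stack several). Each event integrates its own speed history starting at
the sample ``v0`` taken at its edge, and events fire strictly in creation
order per nozzle, so open/close commands alternate.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Sequence

import numpy as np

__all__ = [
    "DelayConfig",
    "SpeedSample",
    "SprayEvent",
    "ValveCommand",
    "HysteresisController",
    "delay_time",
    "activation_distance",
    "trapezoid_distance",
    "push_event",
    "on_speed_sample",
]

#: Default feedback period, seconds (10 Hz speed telemetry).
DEFAULT_H = 0.1
#: Relative tolerance on sample spacing before erroring.
SPACING_RTOL = 0.01


@dataclass(frozen=True)
class DelayConfig:
    """Latency budget and compensation margin.

    t1: equipment processing, t2: solenoid valve response, t3: droplet
    settling (seconds). L3 is an extra compensation margin (meters) against
    speed-measurement error. ``comp_mode`` selects the L2 sign convention
    (see module docstring).
    """

    t1: float = 0.05
    t2: float = 0.06
    t3: float = 0.05
    L3: float = 0.01
    comp_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if min(self.t1, self.t2, self.t3) < 0:
            raise ValueError("delays must be >= 0")
        if self.comp_mode not in ("as_printed", "lead"):
            raise ValueError("comp_mode must be 'as_printed' or 'lead'")


@dataclass(frozen=True)
class SpeedSample:
    t: float
    v: float

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class SprayEvent:
    """One armed open or close action.

    ``A`` is the target distance; ``M`` the private trapezoidal
    accumulator (starts at 0, nondecreasing); ``k`` counts feedback
    samples folded in; ``last_v`` is the most recent speed this event has
    seen (``v0`` until the first sample arrives).
    """

    nozzle: int
    kind: str
    A: float
    created_t: float
    v0: float
    M: float = 0.0
    k: int = 0
    last_v: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("open", "close"):
            raise ValueError("kind must be 'open' or 'close'")
        self.last_v = self.v0


@dataclass(frozen=True)
class ValveCommand:
    nozzle: int
    action: str
    t: float


def delay_time(cfg: DelayConfig) -> float:
    """Total command-to-liquid delay t_c = t1 + t2 + t3."""
    return cfg.t1 + cfg.t2 + cfg.t3


def activation_distance(
    L1: float,
    v0: float,
    t_c: float,
    L3: float = 0.0,
    comp_mode: str = "as_printed",
) -> float:
    """Distance after the edge at which the valve command must fire.

    ``as_printed``: L1 + v0*t_c + L3. ``lead``: L1 - v0*t_c + L3, floored
    at zero (the command cannot fire before the edge).
    """
    if L1 <= 0:
        raise ValueError("L1 must be > 0")
    L2 = v0 * t_c
    if comp_mode == "as_printed":
        return L1 + L2 + L3
    if comp_mode == "lead":
        return max(0.0, L1 - L2 + L3)
    raise ValueError("comp_mode must be 'as_printed' or 'lead'")


def trapezoid_distance(samples: Sequence[SpeedSample]) -> float:
    """Composite trapezoidal distance over uniformly spaced speed samples.

    Returns (h/2) * [v_0 + v_n + 2 * sum(v_1 .. v_{n-1})] with h taken
    from the first spacing. Fewer than two samples integrate to 0 (with a
    warning); spacing deviating more than 1% from h is an error.
    """
    if len(samples) < 2:
        warnings.warn("trapezoid_distance needs >= 2 samples; returning 0", stacklevel=2)
        return 0.0
    t = np.array([s.t for s in samples], dtype=float)
    v = np.array([s.v for s in samples], dtype=float)
    dt = np.diff(t)
    h = dt[0]
    if h <= 0 or np.any(np.abs(dt - h) > SPACING_RTOL * h):
        raise ValueError("speed samples must be uniformly spaced")
    return float((h / 2.0) * (v[0] + v[-1] + 2.0 * v[1:-1].sum()))


# ---------------------------------------------------------------------------
# event queues


def push_event(
    queue: Deque[SprayEvent],
    nozzle: int,
    kind: str,
    A: float,
    created_t: float,
    v0: float,
) -> SprayEvent:
    """Arm a new event at the tail of a nozzle's FIFO queue.

    The accumulator starts from zero: each determination flip restarts its
    own integration clock.
    """
    ev = SprayEvent(nozzle=nozzle, kind=kind, A=A, created_t=created_t, v0=v0)
    queue.append(ev)
    return ev


def on_speed_sample(
    queues: dict[int, Deque[SprayEvent]], sample: SpeedSample, h: float = DEFAULT_H
) -> list[ValveCommand]:
    """Advance every pending event by one feedback sample; fire ripe ones.

    Each event gains the trapezoid increment (h/2) * (last_v + v) against
    its own history. Events fire in strict creation order per nozzle: the
    queue head fires while M >= A, so several commands can leave one queue
    on a single sample, but a ripe event never overtakes an unripe older
    one (open/close alternation is preserved).
    """
    fired: list[tuple[float, ValveCommand]] = []
    for nozzle, queue in queues.items():
        for ev in queue:
            ev.M += (h / 2.0) * (ev.last_v + sample.v)
            ev.last_v = sample.v
            ev.k += 1
        while queue and queue[0].M >= queue[0].A:
            ev = queue.popleft()
            fired.append(
                (ev.created_t, ValveCommand(nozzle=nozzle, action=ev.kind, t=sample.t))
            )
    fired.sort(key=lambda item: item[0])
    return [cmd for _, cmd in fired]


class HysteresisController:
    """Ties the pieces together for a multi-nozzle bar.

    Feed it edge events (:meth:`on_edge`) and 10 Hz speed samples
    (:meth:`on_sample`); it returns the valve commands that fire.
    """

    def __init__(
        self,
        n_nozzles: int,
        delays: DelayConfig,
        L1: float,
        h: float = DEFAULT_H,
    ) -> None:
        self.delays = delays
        self.L1 = L1
        self.h = h
        self.t_c = delay_time(delays)
        self.queues: dict[int, Deque[SprayEvent]] = {
            i: deque() for i in range(n_nozzles)
        }
        self._last_sample_t: float | None = None

    def on_edge(self, lane: int, kind: str, t: float, v0: float) -> SprayEvent:
        """Arm the open (rising) or close (falling) event for a lane edge.

        In lead mode the margin L3 is applied with the sign that widens the
        burst — open L3 early, close L3 late — which is what a safety
        margin "to ensure the hit and spraying rate" has to do: a
        symmetric shift would leave the burst no wider than the weed and a
        single unlucky 10 Hz firing quantum could slide it clean off a
        small weed. In as_printed mode L3 is added for both actions,
        exactly as the printed formula has it.
        """
        action = "open" if kind == "rising" else "close"
        if self.delays.comp_mode == "lead":
            margin = -self.delays.L3 if action == "open" else self.delays.L3
            A = activation_distance(self.L1, v0, self.t_c, margin, "lead")
        else:
            A = activation_distance(
                self.L1, v0, self.t_c, self.delays.L3, "as_printed"
            )
        return push_event(self.queues[lane], lane, action, A, t, v0)

    def on_sample(self, sample: SpeedSample) -> list[ValveCommand]:
        if self._last_sample_t is not None:
            dt = sample.t - self._last_sample_t
            if abs(dt - self.h) > SPACING_RTOL * self.h:
                raise ValueError(
                    f"feedback sample spacing {dt:.4f}s deviates more than "
                    f"{SPACING_RTOL:.0%} from h={self.h}s"
                )
        self._last_sample_t = sample.t
        return on_speed_sample(self.queues, sample, self.h)

    @property
    def pending(self) -> int:
        return sum(len(q) for q in self.queues.values())
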