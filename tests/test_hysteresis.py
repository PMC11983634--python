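"""Delay arithmetic, trapezoidal integration and the FIFO event queues."""

import math
from collections import deque

import numpy as np
import pytest

from spotspray.hysteresis import (
    DelayConfig,
    HysteresisController,
    SpeedSample,
    activation_distance,
    delay_time,
    on_speed_sample,
    push_event,
    trapezoid_distance,
)

H = 0.1


def samples_from(values, t0=0.0, h=H):
    return [SpeedSample(t=t0 + k * h, v=float(v)) for k, v in enumerate(values)]


@pytest.mark.parametrize(
    "t1,t2,t3,expected",
    [(0.03, 0.02, 0.01, 0.06), (0.0, 0.0, 0.0, 0.0), (0.1, 0.05, 0.15, 0.30)],
)
def test_delay_time_is_the_sum(t1, t2, t3, expected):
    assert delay_time(DelayConfig(t1=t1, t2=t2, t3=t3)) == pytest.approx(expected)


class TestActivationDistance:
    def test_as_printed_adds_the_delay_travel(self):
        assert activation_distance(1.0, 0.5, 0.2, 0.05, "as_printed") == pytest.approx(1.15)

    def test_modes_coincide_without_delay_or_margin(self):
        for mode in ("as_printed", "lead"):
            assert activation_distance(0.7, 0.5, 0.0, 0.0, mode) == pytest.approx(0.7)

    def test_lead_subtracts_the_delay_travel(self):
        assert activation_distance(0.5, 0.5, 0.2, 0.0, "lead") == pytest.approx(0.40)

    def test_lead_floors_at_zero(self):
        assert activation_distance(0.1, 2.0, 0.2, 0.0, "lead") == 0.0

    def test_nonpositive_l1_is_a_config_error(self):
        with pytest.raises(ValueError):
            activation_distance(-0.1, 0.5, 0.2)


class TestTrapezoidDistance:
    def test_exact_for_constant_speed(self):
        assert trapezoid_distance(samples_from([0.5] * 11)) == pytest.approx(0.5)

    def test_exact_for_linear_speed(self):
        assert trapezoid_distance(samples_from(np.linspace(0, 1, 11))) == pytest.approx(0.5)

    def test_sine_matches_closed_form_and_numpy_oracle(self):
        t = np.arange(0, 1.0 + 1e-9, H)
        v = np.sin(t)
        got = trapezoid_distance(samples_from(v))
        assert got == pytest.approx(1 - math.cos(1.0), abs=1e-3)
        assert got == pytest.approx(np.trapezoid(v, t), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_numpy_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        v = rng.uniform(0, 1, n)
        t = np.arange(n) * H
        assert trapezoid_distance(samples_from(v)) == pytest.approx(
            np.trapezoid(v, t), abs=1e-12
        )

    def test_short_trace_integrates_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert trapezoid_distance(samples_from([0.5])) == 0.0

    def test_nonuniform_spacing_rejected(self):
        bad = [SpeedSample(0.0, 0.5), SpeedSample(0.1, 0.5), SpeedSample(0.25, 0.5)]
        with pytest.raises(ValueError):
            trapezoid_distance(bad)


class TestEventQueue:
    def test_first_rising_edge_arms_one_open_event(self):
        q = deque()
        ev = push_event(q, nozzle=0, kind="open", A=0.3, created_t=0.0, v0=0.5)
        assert list(q) == [ev] and ev.M == 0.0 and ev.k == 0

    def test_open_then_close_preserved_in_order(self):
        q = deque()
        push_event(q, 0, "open", 0.3, 0.0, 0.5)
        push_event(q, 0, "close", 0.3, 0.2, 0.5)
        assert [e.kind for e in q] == ["open", "close"]

    @pytest.mark.parametrize("seed", range(10))
    def test_creation_order_matches_list_semantics_across_nozzles(self, seed):
        rng = np.random.default_rng(seed)
        queues = {n: deque() for n in range(4)}
        mirror = {n: [] for n in range(4)}
        for i in range(50):
            n = int(rng.integers(4))
            kind = "open" if len(mirror[n]) % 2 == 0 else "close"
            push_event(queues[n], n, kind, float(rng.uniform(0, 0.5)), 0.01 * i, 0.5)
            mirror[n].append(kind)
        for n in range(4):
            assert [e.kind for e in queues[n]] == mirror[n]

    def test_event_fires_on_first_sample_reaching_target(self):
        # A = 0.05 at constant 0.5 m/s: first increment is 0.05 -> fires
        q = {0: deque()}
        push_event(q[0], 0, "open", 0.05, 0.0, 0.5)
        cmds = on_speed_sample(q, SpeedSample(0.1, 0.5), h=H)
        assert len(cmds) == 1 and cmds[0].action == "open" and cmds[0].t == 0.1
        assert len(q[0]) == 0

    def test_zero_target_fires_on_any_sample(self):
        q = {0: deque()}
        push_event(q[0], 0, "open", 0.0, 0.0, 0.0)
        assert len(on_speed_sample(q, SpeedSample(0.1, 0.0), h=H)) == 1

    def test_no_pending_events_no_commands(self):
        assert on_speed_sample({0: deque()}, SpeedSample(0.1, 0.5), h=H) == []

    def test_constant_speed_fires_after_ceil_a_over_vh_samples(self):
        v = 0.4
        for A in (0.01, 0.04, 0.08, 0.3, 0.301):
            q = {0: deque()}
            push_event(q[0], 0, "open", A, 0.0, v)
            n_fired = None
            for k in range(1, 100):
                if on_speed_sample(q, SpeedSample(k * H, v), h=H):
                    n_fired = k
                    break
            assert n_fired == math.ceil(A / (v * H))

    def test_larger_target_never_fires_earlier(self):
        rng = np.random.default_rng(4)
        vs = rng.uniform(0.3, 0.6, 100)
        fire_times = []
        for A in (0.1, 0.2, 0.2000001, 0.5):
            q = {0: deque()}
            push_event(q[0], 0, "open", A, 0.0, float(vs[0]))
            fired = None
            for k, v in enumerate(vs[1:], start=1):
                if on_speed_sample(q, SpeedSample(k * H, float(v)), h=H):
                    fired = k
                    break
            fire_times.append(fired)
        assert fire_times == sorted(fire_times)


class TestController:
    def test_alternation_and_accumulator_on_random_streams(self):
        """Random edges + random speeds: FIFO discipline and M == its own
        trapezoid history, checked against the standalone integrator."""
        rng = np.random.default_rng(11)
        ctrl = HysteresisController(n_nozzles=3, delays=DelayConfig(), L1=0.2)
        histories = {}  # event id -> list of speeds it has seen
        pending_kind = {n: "rising" for n in range(3)}
        commands = []
        t = 0.0
        v = 0.45
        for step in range(300):
            t = round(t + H, 10)
            v = float(np.clip(v + rng.uniform(-0.02, 0.02), 0.3, 0.6))
            if rng.random() < 0.25:
                lane = int(rng.integers(3))
                ev = ctrl.on_edge(lane, pending_kind[lane], t, v)
                pending_kind[lane] = "falling" if pending_kind[lane] == "rising" else "rising"
                histories[id(ev)] = [v]
            fired = ctrl.on_sample(SpeedSample(t, v))
            for q in ctrl.queues.values():
                for ev in q:
                    histories[id(ev)].append(v)
                    expected = trapezoid_distance(samples_from(histories[id(ev)]))
                    assert ev.M == pytest.approx(expected, abs=1e-12)
            commands.extend(fired)
        per_nozzle = {n: [c.action for c in commands if c.nozzle == n] for n in range(3)}
        for actions in per_nozzle.values():
            assert actions[::2] == ["open"] * len(actions[::2])
            assert actions[1::2] == ["close"] * len(actions[1::2])

    def test_sample_spacing_tolerance(self):
        ctrl = HysteresisController(n_nozzles=1, delays=DelayConfig(), L1=0.2)
        ctrl.on_sample(SpeedSample(0.0, 0.5))
        ctrl.on_sample(SpeedSample(0.1005, 0.5))  # 0.5% off: tolerated
        with pytest.raises(ValueError):
            ctrl.on_sample(SpeedSample(0.31, 0.5))  # ~5% off: rejected
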