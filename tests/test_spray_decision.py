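"""Lane assignment, cluster merging and grid-determination edges.

The merge operation is checked against an independent morphological
oracle: intervals rasterized on a 1 mm grid, binary-closed with a
structuring element of width d_min, components read back. d_min is kept
off the millimeter lattice so the merge/keep boundary case (gap exactly
d_min) never hinges on rasterization.
"""

import numpy as np
import pytest
from scipy import ndimage

from spotspray.detection import DetectionBox
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

GRID_STEP = 0.0005


def closing_oracle(intervals, d_min, step=GRID_STEP):
    """Fine-grid morphological closing of a union of intervals.

    Interval endpoints live on a 1 mm lattice; the raster is twice as fine
    and lattice-aligned, so a gap of exactly d_min (never representable
    with the off-lattice d_min used below) is the only ambiguous case and
    it cannot occur.
    """
    lo = np.floor((min(a for a, _ in intervals) - 2 * d_min) / step) * step
    hi = max(b for _, b in intervals) + 2 * d_min
    x = lo + step * np.arange(int((hi - lo) / step) + 1)
    occupied = np.zeros(len(x), dtype=bool)
    for a, b in intervals:
        occupied |= (x >= a - 1e-9) & (x <= b + 1e-9)
    radius = int(round((d_min / 2) / step))
    closed = ndimage.binary_closing(occupied, structure=np.ones(2 * radius + 1))
    labels, n = ndimage.label(closed)
    out = []
    for i in range(1, n + 1):
        pts = x[labels == i]
        out.append((pts[0], pts[-1]))
    return out


def box(x0, x1, y0=0.1, y1=0.2):
    return DetectionBox(lane_span=(x0, x1), travel_span=(y0, y1))


class TestAssignLanes:
    def test_multi_lane_box_appears_in_every_overlapped_lane(self, geom):
        # lanes 3: [0.69, 0.92], 4: [0.92, 1.15]
        lanes = assign_lanes([box(0.80, 0.95)], geom)
        hit = [i for i, iv in enumerate(lanes) if iv]
        assert hit == [3, 4]

    def test_boundary_box_lands_in_both_adjacent_lanes(self, geom):
        lanes = assign_lanes([box(2 * 0.23, 2 * 0.23 + 0.05)], geom)
        hit = [i for i, iv in enumerate(lanes) if iv]
        assert hit == [1, 2]

    def test_empty_input_gives_empty_lanes(self, geom):
        assert all(iv == [] for iv in assign_lanes([], geom))

    def test_box_outside_lane_range_ignored_with_warning(self, geom, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="spotspray.spray_decision"):
            lanes = assign_lanes([box(5.0, 5.2)], geom)
        assert all(iv == [] for iv in lanes)
        assert "outside lane range" in caplog.text


class TestExpandAndMerge:
    def test_gap_below_dmin_merges(self, resp):
        assert expand_and_merge([(0.0, 0.05), (0.09, 0.14)], resp) == [(0.0, 0.14)]

    def test_gap_at_or_above_dmin_kept(self, resp):
        ivs = [(0.0, 0.05), (0.11, 0.16)]
        assert expand_and_merge(ivs, resp) == ivs
        # exactly d_min apart: the valve can just respond -> kept separate
        assert expand_and_merge([(0.0, 0.05), (0.10, 0.15)], resp) == [
            (0.0, 0.05),
            (0.10, 0.15),
        ]

    def test_single_interval_is_fixed_point(self, resp):
        assert expand_and_merge([(0.2, 0.31)], resp) == [(0.2, 0.31)]

    @pytest.mark.parametrize("case", range(100))
    def test_matches_morphological_closing_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        d_min = 0.0503  # off the 1 mm lattice: no rasterized boundary ties
        n = int(rng.integers(1, 8))
        starts = np.round(rng.uniform(0.0, 0.5, n), 3)
        lens = np.round(rng.uniform(0.003, 0.1, n), 3)
        ivs = [(float(a), float(a + l)) for a, l in zip(starts, lens)]
        got = expand_and_merge(ivs, ResponseConfig(d_min=d_min))
        expected = closing_oracle(ivs, d_min)
        assert len(got) == len(expected)
        for (a, b), (ea, eb) in zip(got, expected):
            assert a == pytest.approx(ea, abs=2 * GRID_STEP)
            assert b == pytest.approx(eb, abs=2 * GRID_STEP)

    @pytest.mark.parametrize("case", range(30))
    def test_merge_soundness_properties(self, case, resp):
        rng = np.random.default_rng(500 + case)
        n = int(rng.integers(1, 12))
        ivs = sorted(
            (float(a), float(a + l))
            for a, l in zip(rng.uniform(0, 1, n), rng.uniform(0.005, 0.12, n))
        )
        merged = expand_and_merge(ivs, resp)
        # every original interval inside exactly one merged interval
        for a, b in ivs:
            hosts = [m for m in merged if m[0] <= a and b <= m[1]]
            assert len(hosts) == 1
        # outer bounds preserved
        assert merged[0][0] == min(a for a, _ in ivs)
        assert merged[-1][1] == max(b for _, b in ivs)
        # all output gaps >= d_min, sorted
        for (_, b1), (a2, _) in zip(merged, merged[1:]):
            assert a2 - b1 >= resp.d_min

    @pytest.mark.parametrize("case", range(15))
    def test_larger_dmin_never_increases_cluster_count(self, case):
        rng = np.random.default_rng(900 + case)
        n = int(rng.integers(2, 10))
        ivs = [
            (float(a), float(a + l))
            for a, l in zip(rng.uniform(0, 1, n), rng.uniform(0.005, 0.08, n))
        ]
        counts = [
            len(expand_and_merge(ivs, ResponseConfig(d_min=d)))
            for d in np.linspace(0.0, 0.3, 25)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestUpdateGrid:
    GRID = (0.93, 0.95)

    def test_no_overlap_no_event(self):
        state = LaneGridState(lane=0)
        state, events = update_grid(state, [(0.1, 0.2)], self.GRID, t=0.0, v0=0.5)
        assert state.determination == 0 and events == []

    def test_entering_interval_emits_rising_edge(self):
        state = LaneGridState(lane=2)
        state, events = update_grid(state, [(0.9, 0.94)], self.GRID, t=1.5, v0=0.4)
        assert state.determination == 1
        assert events == [EdgeEvent(lane=2, kind="rising", t=1.5, v0=0.4)]

    def test_two_passing_clusters_emit_two_edge_pairs(self):
        """Two merged clusters sweep the band; brute-force frame check."""
        grid = self.GRID
        clusters = [(0.0, 0.06), (0.14, 0.20)]  # gap 0.08 >= d_min
        v, dt = 0.5, 1 / 60
        state = LaneGridState(lane=0)
        events = []
        for k in range(int(3.0 / dt)):
            t = k * dt
            moved = [(a + v * t, b + v * t) for a, b in clusters]
            state, evs = update_grid(state, moved, grid, t, v)
            # oracle: determination == brute-force overlap check
            brute = int(any(a <= grid[1] and grid[0] <= b for a, b in moved))
            assert state.determination == brute
            events.extend(evs)
        kinds = [e.kind for e in events]
        assert kinds == ["rising", "falling", "rising", "falling"]

    @pytest.mark.parametrize("seed", range(10))
    def test_edges_alternate_and_balance_on_random_passes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        starts = np.sort(rng.uniform(0, 1.5, n))
        ivs = [(float(a), float(a + rng.uniform(0.02, 0.1))) for a in starts]
        merged = expand_and_merge(ivs, ResponseConfig(d_min=0.05))
        v, dt = float(rng.uniform(0.3, 0.6)), 1 / 60
        state = LaneGridState(lane=0)
        events = []
        for k in range(int(6.0 / dt)):
            t = k * dt
            moved = [(a + v * t, b + v * t) for a, b in merged]
            state, evs = update_grid(state, moved, self.GRID, t, v)
            events.extend(evs)
        kinds = [e.kind for e in events]
        assert kinds[::2] == ["rising"] * (len(kinds) // 2)
        assert kinds[1::2] == ["falling"] * (len(kinds) // 2)
        assert len(kinds) % 2 == 0  # every pass completes


def test_geometry_validation():
    with pytest.raises(ValueError):
        GeometryConfig(L1=-0.1)
    with pytest.raises(ValueError):
        GeometryConfig(grid_y=0.99, grid_depth=0.05, view_len=1.0)
    assert ResponseConfig.from_valve(v_nominal=0.5, f_valve=10.0).d_min == 0.05
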