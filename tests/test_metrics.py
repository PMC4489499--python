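"""Metric computations: kinematics, occupancy, switches, page use."""

import math

import numpy as np
import pytest

from atelier import (
    PageGeometry,
    Stroke,
    StudioConfig,
    compare_sessions,
    compute_metrics,
    occupancy_metrics,
    run,
    session_kinematics,
    stroke_length,
    stroke_occupancy_metrics,
    switch_counts,
)
from atelier.metrics import coverage_mask, page_geometry_metrics

from conftest import make_record, simple_stroke_events


def stroke_from(points, t0=0.0, t1=1.0, pressure=0.5, color="red",
                tool="pencil"):
    pts = np.asarray(points, dtype=float)
    ts = np.linspace(t0, t1, len(pts))
    samples = np.column_stack([ts, pts, np.full(len(pts), pressure)])
    return Stroke(samples, color, tool)


class TestStrokeLength:
    def test_two_five_cm_segments(self):
        s = stroke_from([(0, 0), (3, 4), (6, 8)])
        assert stroke_length(s) == pytest.approx(10.0)

    def test_single_sample_is_zero(self):
        s = stroke_from([(2, 2)])
        assert stroke_length(s) == 0.0

    def test_noisy_arc_matches_pairwise_sum_oracle(self):
        rng = np.random.default_rng(42)
        theta = np.sort(rng.uniform(0, math.pi, 1000))
        pts = np.column_stack([5 + 3 * np.cos(theta) + rng.normal(0, .01, 1000),
                               5 + 3 * np.sin(theta) + rng.normal(0, .01, 1000)])
        s = stroke_from(pts)
        oracle = sum(math.hypot(pts[i + 1, 0] - pts[i, 0],
                                pts[i + 1, 1] - pts[i, 1])
                     for i in range(len(pts) - 1))
        assert stroke_length(s) == pytest.approx(oracle, rel=1e-12)


class TestSessionKinematics:
    def test_single_stroke_velocity(self):
        s = stroke_from([(0, 0), (10, 0)], t0=0.0, t1=2.0)
        kin = session_kinematics([s])
        assert kin.avg_velocity == pytest.approx(5.0)

    def test_constant_pressure_recovered(self):
        s = stroke_from([(0, 0), (5, 0), (10, 0)], pressure=0.7)
        assert session_kinematics([s]).avg_pressure == pytest.approx(0.7)

    def test_two_stroke_hand_computation(self):
        s1 = stroke_from([(0, 0), (10, 0)], t0=0.0, t1=2.0)
        s2 = stroke_from([(0, 5), (20, 5)], t0=3.0, t1=5.0)
        kin = session_kinematics([s1, s2])
        assert kin.avg_velocity == pytest.approx(7.5)
        assert kin.avg_stroke_length == pytest.approx(15.0)
        assert kin.strokes_per_second == pytest.approx(0.5)

    def test_gradient_is_displacement_direction(self):
        # drawn upward on screen: dy negative, angle +90
        s = stroke_from([(5, 10), (5, 2)])
        assert session_kinematics([s]).avg_gradient == pytest.approx(90.0)

    def test_degenerate_zero_duration_flags(self):
        s = stroke_from([(1, 1)], t0=1.0, t1=1.0)
        kin = session_kinematics([s])
        assert kin.degenerate
        assert kin.avg_velocity == 0.0


class TestOccupancy:
    def single_stroke_record(self):
        evs = [dict(t=0.0, kind="session_start"),
               dict(t=0.5, kind="select_color", color="red"),
               dict(t=0.5, kind="select_tool", tool="pencil")]
        evs += simple_stroke_events(3.0, 6.0)
        evs += [dict(t=9.0, kind="session_end")]
        return make_record(evs)

    def test_single_category_is_hundred_percent(self):
        rec = self.single_stroke_record()
        m = compute_metrics(rec)
        assert m.color_pct["red"] == pytest.approx(100.0)
        assert m.tool_pct["pencil"] == pytest.approx(100.0)
        assert m.cross_sections[("red", "pencil")] == pytest.approx(
            m.drawing_time)

    def test_drawing_idle_split(self):
        rec = self.single_stroke_record()
        m = compute_metrics(rec)
        assert m.drawing_pct == pytest.approx(100.0 * 3 / 9)
        assert m.idle_pct == pytest.approx(100.0 * 6 / 9)
        assert m.selecting_time == pytest.approx(2.5)  # select at 0.5 → pen 3.0

    def test_top_left_stroke_is_all_q1(self):
        rec = self.single_stroke_record()  # samples run (1,1)→(3,1)
        m = compute_metrics(rec)
        assert m.quarter_pct["Q1"] == pytest.approx(100.0)

    def test_trace_and_direct_paths_agree(self, suite):
        for name, rec, _ in suite[:6]:
            a = occupancy_metrics(run(rec))
            b = stroke_occupancy_metrics(rec)
            assert a.drawing_time == pytest.approx(b.drawing_time, abs=1e-9)
            assert a.selecting_time == pytest.approx(b.selecting_time, abs=1e-9)
            for key in set(a.color_time) | set(b.color_time):
                assert a.color_time.get(key, 0.0) == pytest.approx(
                    b.color_time.get(key, 0.0), abs=1e-9), (name, key)
            for key in set(a.quarter_time) | set(b.quarter_time):
                assert a.quarter_time.get(key, 0.0) == pytest.approx(
                    b.quarter_time.get(key, 0.0), abs=1e-9), (name, key)


class TestSwitchCounts:
    def make_strokes(self, colors, tools=None):
        tools = tools or ["pencil"] * len(colors)
        return [stroke_from([(1, 1), (2, 1)], t0=i, t1=i + 0.5, color=c,
                            tool=t)
                for i, (c, t) in enumerate(zip(colors, tools))]

    def test_hand_counted_example(self, config):
        sw = switch_counts(self.make_strokes(["red", "red", "blue", "red"]),
                           config)
        assert sw.color_switches == 2
        assert sw.switches_per_color == pytest.approx(1.0)
        assert sw.colors_used_pct == pytest.approx(20.0)

    def test_constant_tool_no_switches(self, config):
        sw = switch_counts(self.make_strokes(["red"] * 5), config)
        assert sw.tool_switches == 0

    def test_random_sequence_matches_bruteforce(self, config):
        rng = np.random.default_rng(7)
        colors = [str(c) for c in
                  rng.choice(list(config.palette), 50)]
        tools = [str(t) for t in rng.choice(list(config.toolset), 50)]
        sw = switch_counts(self.make_strokes(colors, tools), config)
        assert sw.color_switches == sum(
            colors[i] != colors[i + 1] for i in range(49))
        assert sw.tool_switches == sum(
            tools[i] != tools[i + 1] for i in range(49))


class TestPageGeometry:
    def test_quarter_assignment(self, geometry):
        assert geometry.quarter(5.0, 5.0) == "Q1"
        assert geometry.quarter(5.0, 15.0) == "Q2"
        assert geometry.quarter(15.0, 5.0) == "Q3"
        assert geometry.quarter(15.0, 15.0) == "Q4"
        # midline ties resolve left/top
        assert geometry.quarter(10.0, 10.0) == "Q1"

    def test_single_horizontal_midline_crossing(self, geometry, config):
        s = stroke_from([(5.0, 5.0), (5.0, 15.0)])
        page = page_geometry_metrics([s], geometry, config)
        assert page.stroke_crossovers_h == 1
        assert page.stroke_crossovers_v == 0

    def test_diagonal_crossing_increments_both(self, geometry, config):
        s = stroke_from([(5.0, 5.0), (15.0, 15.0)])
        page = page_geometry_metrics([s], geometry, config)
        assert page.stroke_crossovers_h == 1
        assert page.stroke_crossovers_v == 1

    def test_start_crossover_requires_edge_adjacency(self, geometry, config):
        q1 = stroke_from([(5, 5), (6, 5)])
        q2 = stroke_from([(5, 15), (6, 15)], t0=2, t1=3)
        q4 = stroke_from([(15, 15), (16, 15)], t0=4, t1=5)
        # Q1→Q2 adjacent, Q2→Q4 adjacent: two start crossovers
        assert page_geometry_metrics([q1, q2, q4], geometry,
                                     config).stroke_start_crossovers == 2
        # Q1→Q4 is diagonal: not a crossover
        assert page_geometry_metrics([q1, q4], geometry,
                                     config).stroke_start_crossovers == 0

    def test_bar_area_matches_bruteforce_raster_oracle(self, geometry):
        config = StudioConfig(raster_cell=0.1)
        s = stroke_from([(5.0, 10.0), (15.0, 10.0)], tool="pencil")
        got = page_geometry_metrics([s], geometry, config).area_used_pct
        # independent pixel-count oracle: loop over all cells
        r = config.tool_width("pencil") / 2.0
        covered = total = 0
        for i in range(200):
            for j in range(200):
                cx, cy = (j + 0.5) * 0.1, (i + 0.5) * 0.1
                px = min(max(cx, 5.0), 15.0)
                total += 1
                if (cx - px) ** 2 + (cy - 10.0) ** 2 <= r * r:
                    covered += 1
        assert got == pytest.approx(covered / total * 100.0, abs=1e-12)

    def test_area_converges_under_raster_refinement(self, geometry):
        s = stroke_from([(5.0, 10.0), (15.0, 10.0)], tool="pastel")
        width = 0.4
        exact = (10.0 * width + math.pi * (width / 2) ** 2) / 400.0 * 100.0
        errs = []
        for cell in (0.4, 0.2, 0.1, 0.05):
            config = StudioConfig(raster_cell=cell)
            got = page_geometry_metrics([s], geometry, config).area_used_pct
            errs.append(abs(got - exact))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.05  # within discretization error of the limit


class TestComputeAndCompare:
    def test_empty_session_all_zero(self):
        rec = make_record([dict(t=0.0, kind="session_start"),
                           dict(t=4.0, kind="session_end")])
        m = compute_metrics(rec)
        assert m.stroke_count == 0
        assert m.drawing_pct == 0.0
        assert m.idle_pct == 100.0
        assert m.degenerate

    def test_metric_invariants_on_fixtures(self, suite):
        for name, rec, _ in suite:
            m = compute_metrics(rec)
            if m.degenerate:
                continue
            assert m.drawing_pct + m.idle_pct == pytest.approx(100.0)
            assert sum(m.quarter_pct.values()) == pytest.approx(100.0)
            assert sum(m.tool_pct.values()) == pytest.approx(100.0)
            assert m.center_pct + m.boundary_pct == pytest.approx(100.0)
            assert m.avg_velocity * m.drawing_time == pytest.approx(
                m.total_stroke_length, rel=1e-9)
            flat = m.flatten()
            for key, val in flat.items():
                if key.endswith("_pct") or ":" in key:
                    assert -1e-9 <= val <= 100.0 + 1e-9, (name, key)

    def test_adding_a_stroke_is_monotone(self, geometry, config):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 2.0)
        base = evs + [dict(t=6.0, kind="session_end")]
        more = (evs + simple_stroke_events(3.0, 4.0, xy0=(8.0, 8.0),
                                           xy1=(12.0, 8.0))
                + [dict(t=6.0, kind="session_end")])
        m0 = compute_metrics(make_record(base))
        m1 = compute_metrics(make_record(more))
        assert m1.stroke_count > m0.stroke_count
        assert m1.total_stroke_length >= m0.total_stroke_length
        assert m1.area_used_pct >= m0.area_used_pct

    def test_compare_session_with_itself(self, fixtures):
        rec, _ = fixtures["three-object"]
        m = compute_metrics(rec)
        table = compare_sessions(m, m)
        assert (table["difference"] == 0).all()
        nonzero = table[table["b"] != 0]
        assert np.allclose(nonzero["ratio"], 1.0)

    def test_compare_row_count_is_field_count(self, fixtures):
        (ra, _), (rb, _) = fixtures["three-object"], fixtures["vertical-mass"]
        ma, mb = compute_metrics(ra), compute_metrics(rb)
        table = compare_sessions(ma, mb)
        assert len(table) == len(ma.flatten())

    def test_compare_mismatched_configs_rejected(self, fixtures):
        rec, _ = fixtures["three-object"]
        m = compute_metrics(rec)
        other = StudioConfig(palette=("red", "blue"),
                             toolset=("pencil",),
                             tool_widths={"pencil": 0.1})
        evs = [dict(t=0.0, kind="session_start"),
               dict(t=1.0, kind="session_end")]
        m2 = compute_metrics(make_record(evs, config=other))
        with pytest.raises(ValueError):
            compare_sessions(m, m2)

    def test_eraser_time_reported_as_pseudo_color(self, fixtures):
        rec, gt = fixtures["three-object"]
        m = compute_metrics(rec)
        assert m.color_time["erase"] == pytest.approx(
            gt.color_time["erase"], rel=1e-9)
        # eraser stroke time does not leak into real-color occupancy
        assert sum(m.color_time.values()) == pytest.approx(m.drawing_time)
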