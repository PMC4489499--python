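"""Statechart model construction, stepping semantics, trace properties."""

import numpy as np
import pytest

from atelier import (
    ArtworkTracker,
    StudioConfig,
    build_artwork_model,
    extract_strokes,
    run,
    validate_configuration,
)
from atelier.session import SessionEvent
from atelier.statechart import StatechartError, gradient_angle, gradient_sector

from conftest import make_record, simple_stroke_events


class TestModel:
    def test_default_color_region_has_ten_children(self, config):
        root = build_artwork_model(config)
        assert len(root.find("Color").children) == 10

    def test_default_tool_region_has_six_children(self, config):
        root = build_artwork_model(config)
        assert len(root.find("Tool").children) == 6

    def test_parametric_palette(self):
        cfg = StudioConfig(palette=("red",), toolset=("pencil",),
                           tool_widths={"pencil": 0.1})
        root = build_artwork_model(cfg)
        assert len(root.find("Color").children) == 1

    def test_empty_palette_rejected(self):
        with pytest.raises(ValueError):
            StudioConfig(palette=())

    def test_painting_has_three_orthogonal_components(self, config):
        root = build_artwork_model(config)
        painting = root.find("Painting")
        assert painting.mode == "parallel"
        assert {c.name for c in painting.children} == {
            "Materials_Selected", "Stroke_Characteristics", "Page_Use"}


class TestGradientConvention:
    @pytest.mark.parametrize("dx,dy,expected_angle,expected_sector", [
        (1.0, 0.0, 0.0, "E"),
        (0.0, -1.0, 90.0, "N"),     # screen y grows downward
        (0.0, 1.0, -90.0, "S"),
        (-1.0, 0.0, 180.0, "W"),
        (1.0, -1.0, 45.0, "NE"),
        (-1.0, 1.0, -135.0, "SW"),
    ])
    def test_angle_and_sector(self, dx, dy, expected_angle, expected_sector):
        ang = gradient_angle(dx, dy)
        assert ang == pytest.approx(expected_angle)
        assert gradient_sector(ang) == expected_sector

    def test_sector_boundary_goes_counter_clockwise(self):
        assert gradient_sector(22.5) == "NE"
        assert gradient_sector(-22.5) == "E"


class TestStep:
    def make_tracker(self):
        rec = make_record([dict(t=0.0, kind="session_start")])
        tracker = ArtworkTracker(rec)
        tracker.step(SessionEvent(t=0.0, kind="session_start"))
        return tracker

    def test_pen_down_activates_eight_leaves(self):
        tracker = self.make_tracker()
        cfg = tracker.step(SessionEvent(t=1.0, kind="pen_down", x=2.0, y=2.0,
                                        pressure=0.5))
        painting_leaves = [s for s in cfg if ":" in s]
        assert len(painting_leaves) == 8
        prefixes = {s.split(":")[0] for s in painting_leaves}
        assert prefixes == {"color", "tool", "velocity", "gradient",
                            "pressure", "size", "quarter", "part"}
        validate_configuration(tracker.model, cfg)

    def test_selection_enters_materials_selecting(self):
        tracker = self.make_tracker()
        cfg = tracker.step(SessionEvent(t=0.5, kind="select_color",
                                        color="blue"))
        assert "Materials_Selecting" in cfg
        assert tracker.pending_color == "blue"

    def test_session_end_turns_session_off(self):
        tracker = self.make_tracker()
        cfg = tracker.step(SessionEvent(t=3.0, kind="session_end"))
        assert "ArtRoomSessionOff" in cfg
        assert "ArtRoomSessionOn" not in cfg

    def test_event_while_off_is_an_error(self):
        rec = make_record([dict(t=0.0, kind="session_start")])
        tracker = ArtworkTracker(rec)
        with pytest.raises(StatechartError):
            tracker.step(SessionEvent(t=0.0, kind="select_color", color="red"))

    def test_pen_up_returns_to_idle(self):
        tracker = self.make_tracker()
        tracker.step(SessionEvent(t=1.0, kind="pen_down", x=2.0, y=2.0,
                                  pressure=0.5))
        cfg = tracker.step(SessionEvent(t=2.0, kind="pen_up", x=2.5, y=2.0,
                                        pressure=0.5))
        assert "Idle" in cfg and "Painting" not in cfg


class TestRun:
    def test_occupancy_conservation_simple_session(self):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(0.5, 2.5)
        evs += [dict(t=3.0, kind="session_end")]
        trace = run(make_record(evs))
        assert trace.occupancy("Painting") == pytest.approx(2.0)
        assert (trace.occupancy("Idle")
                + trace.occupancy("Materials_Selecting")) == pytest.approx(1.0)
        assert trace.occupancy("ArtWork") == pytest.approx(3.0)

    def test_empty_session_is_single_idle_interval(self):
        trace = run(make_record([dict(t=0.0, kind="session_start"),
                                 dict(t=5.0, kind="session_end")]))
        idle = trace.intervals_for("Idle")
        assert len(idle) == 1
        assert (idle[0].t_start, idle[0].t_end) == (0.0, 5.0)

    def test_vertical_stroke_occupies_vertical_gradient_sector(self):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 3.0, xy0=(5.0, 2.0), xy1=(5.0, 12.0),
                                    n=21)
        evs += [dict(t=4.0, kind="session_end")]
        trace = run(make_record(evs))
        south = trace.occupancy("gradient:S")  # drawn downward on screen
        assert south == pytest.approx(trace.occupancy("Painting"))

    def test_determinism_identical_record_identical_trace(self, fixtures):
        rec, _ = fixtures["three-object"]
        t1, t2 = run(rec), run(rec)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_region_consistency_throughout(self, fixtures):
        for name, (rec, _) in fixtures.items():
            run(rec, validate=True)  # raises on any inconsistent configuration

    def test_trace_tiles_each_region(self, fixtures):
        rec, _ = fixtures["three-object"]
        trace = run(rec)
        root = build_artwork_model(rec.config)
        # child occupancy of every exclusive region sums to its parent's
        for node in root.walk():
            if node.mode != "exclusive" or node.name == "ArtRoom":
                continue
            parent_occ = trace.occupancy(node.name)
            child_occ = sum(trace.occupancy(c.name) for c in node.children)
            assert child_occ == pytest.approx(parent_occ, abs=1e-9), node.name
        assert trace.occupancy("ArtWork") == pytest.approx(
            trace.t_end - trace.t_start)

    def test_intervals_stay_inside_session(self, suite):
        for name, rec, _ in suite[:8]:
            trace = run(rec)
            for iv in trace.intervals:
                assert trace.t_start <= iv.t_start <= iv.t_end <= trace.t_end

    def test_velocity_leaves_match_brute_force_oracle(self, suite):
        """Velocity-class occupancy equals direct reclassification of every
        sample window from raw stroke samples and the thresholds."""
        for name, rec, _ in suite[:8]:
            trace = run(rec)
            lo, hi = rec.config.velocity_thresholds
            expected = {"low": 0.0, "medium": 0.0, "high": 0.0}
            for s in extract_strokes(rec):
                if len(s) < 2:
                    continue
                t = s.samples[:, 0]
                dt = np.diff(t)
                seg = np.linalg.norm(np.diff(s.xy, axis=0), axis=1)
                v = seg / dt
                for i in range(len(dt)):
                    vi = v[max(0, i - 1)]  # first window inherits the second
                    cls = "low" if vi < lo else ("high" if vi > hi else "medium")
                    expected[cls] += dt[i]
            for cls, want in expected.items():
                got = trace.occupancy(f"velocity:{cls}")
                assert got == pytest.approx(want, abs=1e-9), (name, cls)
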