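"""Session format: parsing, validation, round trips, stroke extraction."""

import json
import math

import numpy as np
import pytest

from atelier import (
    PageGeometry,
    SessionEvent,
    SessionRecord,
    StudioConfig,
    extract_strokes,
    read_session,
    write_session,
)
from atelier.session import SessionFormatError

from conftest import make_record, simple_stroke_events


def events_basic():
    return [
        dict(t=0.0, kind="session_start"),
        dict(t=0.2, kind="select_color", color="red"),
        dict(t=0.3, kind="select_tool", tool="pencil"),
        dict(t=1.0, kind="pen_down", x=1.0, y=1.0, pressure=0.5),
        dict(t=1.5, kind="pen_move", x=2.0, y=1.0, pressure=0.5),
        dict(t=2.0, kind="pen_up", x=3.0, y=1.0, pressure=0.5),
        dict(t=5.0, kind="session_end"),
    ]


class TestReadWrite:
    def test_basic_stream_counts(self, tmp_path):
        rec = make_record(events_basic())
        path = tmp_path / "s.jsonl"
        write_session(rec, path)
        back = read_session(path)
        assert len(back.events) == 7
        assert len(extract_strokes(back)) == 1

    def test_write_read_write_is_byte_identical(self, tmp_path):
        rec = make_record(events_basic())
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_session(rec, p1)
        write_session(read_session(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_two_writes_identical(self, tmp_path):
        rec = make_record(events_basic())
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_session(rec, p1)
        write_session(rec, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_line_names_line_number(self, tmp_path):
        rec = make_record(events_basic())
        path = tmp_path / "s.jsonl"
        write_session(rec, path)
        lines = path.read_text().splitlines()
        lines[3] = lines[3][:-2] + "!!"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SessionFormatError, match="line 4"):
            read_session(path)

    def test_unknown_color_rejected(self, tmp_path):
        path = tmp_path / "s.jsonl"
        header = {"geometry": {"width": 20.0, "height": 20.0}}
        ev = {"t": 0.0, "kind": "session_start"}
        bad = {"t": 1.0, "kind": "select_color", "color": "chartreuse"}
        path.write_text("\n".join(json.dumps(o) for o in (header, ev, bad)))
        with pytest.raises(SessionFormatError, match="chartreuse"):
            read_session(path)

    def test_nan_coordinate_refused(self):
        with pytest.raises(ValueError):
            SessionEvent(t=0.0, kind="pen_down", x=math.nan, y=1.0,
                         pressure=0.5)

    def test_write_refuses_nonfinite_smuggled_values(self, tmp_path):
        ev = SessionEvent.model_construct(t=1.0, kind="pen_down", x=math.inf,
                                          y=1.0, pressure=0.5, color=None,
                                          tool=None)
        rec = SessionRecord.model_construct(
            geometry=PageGeometry(width=20, height=20),
            config=StudioConfig(), meta=None, events=(ev,))
        rec = rec.model_copy(update={"meta": make_record([]).meta})
        with pytest.raises(SessionFormatError):
            write_session(rec, tmp_path / "bad.jsonl")


class TestStreamValidation:
    def test_pen_move_before_pen_down_rejected(self):
        with pytest.raises(ValueError, match="outside a stroke"):
            make_record([
                dict(t=0.0, kind="session_start"),
                dict(t=1.0, kind="pen_move", x=1.0, y=1.0, pressure=0.5),
            ])

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            make_record([
                dict(t=0.0, kind="session_start"),
                dict(t=2.0, kind="select_color", color="red"),
                dict(t=1.0, kind="select_color", color="blue"),
            ])

    def test_session_start_must_lead(self):
        with pytest.raises(ValueError, match="session_start"):
            make_record([dict(t=0.0, kind="select_color", color="red")])

    def test_off_page_coordinates_rejected(self):
        with pytest.raises(ValueError, match="off page"):
            make_record([
                dict(t=0.0, kind="session_start"),
                dict(t=1.0, kind="pen_down", x=25.0, y=1.0, pressure=0.5),
            ])

    def test_pen_event_payload_required(self):
        with pytest.raises(ValueError):
            SessionEvent(t=0.0, kind="pen_down", x=1.0, y=1.0)


class TestExtractStrokes:
    def test_two_pairs_two_strokes(self):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 2.0)
        evs += simple_stroke_events(3.0, 4.0, xy0=(5.0, 5.0), xy1=(7.0, 5.0))
        evs += [dict(t=5.0, kind="session_end")]
        strokes = extract_strokes(make_record(evs))
        assert len(strokes) == 2
        assert strokes[0].t0 < strokes[1].t0

    def test_point_touch_is_single_sample_zero_length(self):
        evs = [
            dict(t=0.0, kind="session_start"),
            dict(t=1.0, kind="pen_down", x=2.0, y=2.0, pressure=0.4),
            dict(t=1.0, kind="pen_up", x=2.0, y=2.0, pressure=0.4),
            dict(t=2.0, kind="session_end"),
        ]
        (s,) = extract_strokes(make_record(evs))
        assert len(s) == 1
        assert s.length() == 0.0

    def test_eraser_selection_attaches_to_stroke(self):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 2.0)
        evs += simple_stroke_events(3.0, 4.0)
        evs += [dict(t=4.5, kind="select_tool", tool="eraser")]
        evs += simple_stroke_events(5.0, 6.0)
        evs += [dict(t=7.0, kind="session_end")]
        strokes = extract_strokes(make_record(evs))
        assert [s.tool for s in strokes] == ["pencil", "pencil", "eraser"]

    def test_defaults_before_first_selection(self, caplog):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 2.0)
        evs += [dict(t=3.0, kind="session_end")]
        with caplog.at_level("WARNING"):
            (s,) = extract_strokes(make_record(evs))
        assert s.color == "yellow"  # first palette entry
        assert s.tool == "pencil"
        assert "default" in caplog.text

    def test_truncated_stream_closes_stroke(self, caplog):
        evs = [dict(t=0.0, kind="session_start")]
        evs += simple_stroke_events(1.0, 2.0)[:-1]  # no pen_up
        with caplog.at_level("WARNING"):
            strokes = extract_strokes(make_record(evs))
        assert len(strokes) == 1
        assert "closing" in caplog.text

    def test_every_pen_sample_in_exactly_one_stroke(self, suite):
        for name, rec, _ in suite:
            n_pen = sum(1 for ev in rec.events
                        if ev.kind in ("pen_down", "pen_move", "pen_up"))
            strokes = extract_strokes(rec)
            n_down = sum(1 for ev in rec.events if ev.kind == "pen_down")
            n_up = sum(1 for ev in rec.events if ev.kind == "pen_up")
            assert len(strokes) == n_down == n_up, name
            # duplicate pen_up samples are deduplicated, never duplicated
            assert sum(len(s) for s in strokes) <= n_pen
            assert sum(len(s) for s in strokes) >= n_pen - len(strokes)
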