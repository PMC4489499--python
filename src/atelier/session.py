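"""Session recordings: the open event-stream format and its domain types.

A drawing session is an ordered stream of timestamped events produced by a
pen tablet: pen_down / pen_move / pen_up samples carrying page coordinates
(cm) and stylus pressure (dimensionless, 0..1), selection events for colors
and tools, and session_start / session_end markers.  The five raw channels
(x, y, pressure, color choice, tool choice) are the only observables; every
behavioral quantity downstream is derived from them.

Files are JSON Lines: line 1 is a header object carrying the page geometry,
the studio configuration (palette, toolset, thresholds) and session
metadata; every subsequent line is one event.  Serialization is canonical
(sorted keys, shortest round-tripping float repr) so write∘read and
read∘write are identities.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterator, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

#: Palette and toolset of the reference studio setup.
DEFAULT_PALETTE = (
    "yellow", "red", "blue", "orange", "violet",
    "green", "black", "white", "pink", "skin",
)
DEFAULT_TOOLSET = ("pencil", "pastel", "oils", "water color", "ink pen", "eraser")

#: Pseudo-color label under which eraser-stroke time is reported.
ERASE_PSEUDO_COLOR = "erase"

EventKind = Literal[
    "session_start", "session_end",
    "pen_down", "pen_move", "pen_up",
    "select_color", "select_tool",
]

PEN_KINDS = frozenset({"pen_down", "pen_move", "pen_up"})


class SessionFormatError(ValueError):
    """Malformed session file or invariant-violating event stream."""


class SessionEvent(BaseModel):
    """One timestamped occurrence in a drawing session.

    ``t`` is seconds since session start.  ``x``/``y``/``pressure`` are
    present exactly for pen events, ``color`` only for select_color and
    ``tool`` only for select_tool.
    """

    model_config = ConfigDict(frozen=True)

    t: float = Field(ge=0)
    kind: EventKind
    x: Optional[float] = None
    y: Optional[float] = None
    pressure: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    color: Optional[str] = None
    tool: Optional[str] = None

    @model_validator(mode="after")
    def _check_payload(self) -> "SessionEvent":
        if self.kind in PEN_KINDS:
            if self.x is None or self.y is None or self.pressure is None:
                raise ValueError(f"{self.kind} event requires x, y and pressure")
            if not (math.isfinite(self.x) and math.isfinite(self.y)):
                raise ValueError("pen coordinates must be finite")
        else:
            if self.x is not None or self.y is not None or self.pressure is not None:
                raise ValueError(f"{self.kind} event must not carry pen fields")
        if (self.kind == "select_color") != (self.color is not None):
            raise ValueError("color payload present iff kind is select_color")
        if (self.kind == "select_tool") != (self.tool is not None):
            raise ValueError("tool payload present iff kind is select_tool")
        return self


class PageGeometry(BaseModel):
    """Drawing page dimensions and its two spatial partitions.

    The page is split into four quarters by its vertical and horizontal
    midlines (Q1 top-left, Q2 bottom-left, Q3 top-right, Q4 bottom-right)
    and, independently, into a centered "center" rectangle (linear scale
    ``center_fraction`` of the page) versus the surrounding "boundary".
    Coordinates follow screen convention: origin top-left, x rightward,
    y downward, units cm.
    """

    model_config = ConfigDict(frozen=True)

    width: float = Field(gt=0)
    height: float = Field(gt=0)
    center_fraction: float = Field(default=0.5, gt=0.0, lt=1.0)

    def quarter(self, x: float, y: float) -> str:
        # Ties on a midline resolve to the left / top quarter.
        left = x <= self.width / 2.0
        top = y <= self.height / 2.0
        if top:
            return "Q1" if left else "Q3"
        return "Q2" if left else "Q4"

    def part(self, x: float, y: float) -> str:
        f = self.center_fraction
        hw = self.width * f / 2.0
        hh = self.height * f / 2.0
        cx, cy = self.width / 2.0, self.height / 2.0
        inside = (cx - hw <= x <= cx + hw) and (cy - hh <= y <= cy + hh)
        return "center" if inside else "boundary"

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


def _default_tool_widths() -> dict[str, float]:
    return {
        "pencil": 0.10,
        "pastel": 0.40,
        "oils": 0.50,
        "water color": 0.60,
        "ink pen": 0.15,
        "eraser": 0.80,
    }


class StudioConfig(BaseModel):
    """Studio configuration: materials on offer and decoding thresholds.

    Velocity classes split at ``velocity_thresholds = (low_max, high_min)``
    cm/s; pressure classes at ``pressure_thresholds`` (tertiles of [0,1] by
    default); stroke-size classes at ``size_thresholds`` cm.  ``tool_widths``
    give the nominal swept width of each tool (cm), used for area coverage
    and playback rendering.  ``raster_cell`` is the grid cell (cm) for the
    page-area-coverage raster.
    """

    model_config = ConfigDict(frozen=True)

    palette: tuple[str, ...] = DEFAULT_PALETTE
    toolset: tuple[str, ...] = DEFAULT_TOOLSET
    velocity_thresholds: tuple[float, float] = (2.0, 10.0)
    pressure_thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    size_thresholds: tuple[float, float] = (2.0, 10.0)
    tool_widths: dict[str, float] = Field(default_factory=_default_tool_widths)
    raster_cell: float = Field(default=0.25, gt=0)
    sample_rate_hint: float = Field(default=100.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "StudioConfig":
        if not self.palette or not self.toolset:
            raise ValueError("palette and toolset must be non-empty")
        if len(set(self.palette)) != len(self.palette):
            raise ValueError("palette names must be unique")
        if len(set(self.toolset)) != len(self.toolset):
            raise ValueError("toolset names must be unique")
        for pair_name in ("velocity_thresholds", "pressure_thresholds", "size_thresholds"):
            lo, hi = getattr(self, pair_name)
            if not lo < hi:
                raise ValueError(f"{pair_name}: low_max must be < high_min")
        for tool in self.toolset:
            if self.tool_widths.get(tool, 0.0) <= 0.0:
                raise ValueError(f"tool {tool!r} needs a positive width")
        return self

    def tool_width(self, tool: str) -> float:
        return self.tool_widths.get(tool, 0.3)


class SessionMeta(BaseModel):
    """Who drew, under which task, with which group labels."""

    model_config = ConfigDict(frozen=True)

    subject: str = "anonymous"
    task: str = "free"
    groups: dict[str, str] = Field(default_factory=dict)


class Stroke:
    """One pen-down→pen-up trajectory with its active color and tool.

    ``samples`` is a float array of shape (n, 4): columns t, x, y, pressure.
    """

    __slots__ = ("samples", "color", "tool")

    def __init__(self, samples: np.ndarray, color: str, tool: str):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 4 or samples.shape[0] < 1:
            raise ValueError("stroke samples must be a (n>=1, 4) array")
        if np.any(np.diff(samples[:, 0]) < 0):
            raise ValueError("stroke sample times must be non-decreasing")
        self.samples = samples
        self.color = color
        self.tool = tool

    @property
    def t0(self) -> float:
        return float(self.samples[0, 0])

    @property
    def t1(self) -> float:
        return float(self.samples[-1, 0])

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    def length(self) -> float:
        """Polyline length: sum of Euclidean inter-sample distances (cm)."""
        if len(self.samples) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))

    def displacement(self) -> tuple[float, float]:
        """(dx, dy) from first to last sample."""
        d = self.xy[-1] - self.xy[0]
        return float(d[0]), float(d[1])

    def __len__(self) -> int:
        return len(self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Stroke(n={len(self)}, color={self.color!r}, tool={self.tool!r}, "
                f"t=[{self.t0:.3f},{self.t1:.3f}])")


class SessionRecord(BaseModel):
    """A full validated drawing session: events + geometry + config + meta."""

    model_config = ConfigDict(frozen=True)

    geometry: PageGeometry
    config: StudioConfig = Field(default_factory=StudioConfig)
    meta: SessionMeta = Field(default_factory=SessionMeta)
    events: tuple[SessionEvent, ...] = ()

    @model_validator(mode="after")
    def _check_stream(self) -> "SessionRecord":
        events = self.events
        if not events:
            return self
        t_prev = -math.inf
        in_stroke = False
        started = ended = False
        for i, ev in enumerate(events):
            where = f"event {i} (t={ev.t}, kind={ev.kind})"
            if ev.t < t_prev:
                raise SessionFormatError(f"decreasing timestamp at {where}")
            t_prev = ev.t
            if ended:
                raise SessionFormatError(f"event after session_end at {where}")
            if ev.kind == "session_start":
                if started:
                    raise SessionFormatError(f"duplicate session_start at {where}")
                if i != 0:
                    raise SessionFormatError("session_start must be the first event")
                started = True
            elif not started:
                raise SessionFormatError("first event must be session_start")
            elif ev.kind == "session_end":
                if in_stroke:
                    raise SessionFormatError(f"session_end inside a stroke at {where}")
                ended = True
            elif ev.kind == "pen_down":
                if in_stroke:
                    raise SessionFormatError(f"nested pen_down at {where}")
                in_stroke = True
            elif ev.kind in ("pen_move", "pen_up"):
                if not in_stroke:
                    raise SessionFormatError(f"{ev.kind} outside a stroke at {where}")
                if ev.kind == "pen_up":
                    in_stroke = False
            elif ev.kind == "select_color":
                if ev.color not in self.config.palette:
                    raise SessionFormatError(f"unknown color {ev.color!r} at {where}")
            elif ev.kind == "select_tool":
                if ev.tool not in self.config.toolset:
                    raise SessionFormatError(f"unknown tool {ev.tool!r} at {where}")
            if ev.kind in PEN_KINDS and not self.geometry.contains(ev.x, ev.y):
                raise SessionFormatError(f"coordinates off page at {where}")
        return self

    @property
    def t_start(self) -> float:
        return self.events[0].t if self.events else 0.0

    @property
    def t_end(self) -> float:
        """End-of-session time: session_end if present, else last event."""
        return self.events[-1].t if self.events else 0.0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# canonical serialization


def _canonical_dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)


def _event_to_obj(ev: SessionEvent) -> dict:
    obj: dict = {"t": ev.t, "kind": ev.kind}
    for key in ("x", "y", "pressure", "color", "tool"):
        val = getattr(ev, key)
        if val is not None:
            obj[key] = val
    return obj


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write ``record`` to ``path`` in canonical JSONL.

    Canonical means: header line first, one event per line, keys sorted,
    floats in shortest round-tripping repr, no NaN/Inf.  Two writes of the
    same record are byte-identical.
    """
    header = {
        "format": "atelier-session/1",
        "geometry": record.geometry.model_dump(),
        "config": record.config.model_dump(),
        "meta": record.meta.model_dump(),
    }
    lines = [_canonical_dumps(header)]
    try:
        lines.extend(_canonical_dumps(_event_to_obj(ev)) for ev in record.events)
    except ValueError as exc:
        raise SessionFormatError(f"non-finite value in event stream: {exc}") from exc
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session(path: str | Path) -> SessionRecord:
    """Read and validate a JSONL session file.

    Raises :class:`SessionFormatError` naming the offending line on parse
    failure, and on any stream-invariant violation.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SessionFormatError(f"{path}: empty session file")
    parsed = []
    for lineno, line in enumerate(lines, start=1):
        try:
            parsed.append(json.loads(line))
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
    header = parsed[0]
    if not isinstance(header, dict) or "geometry" not in header:
        raise SessionFormatError(f"{path}: line 1 must be a header object with geometry")
    try:
        geometry = PageGeometry(**header["geometry"])
        config = StudioConfig(**header.get("config", {}))
        meta = SessionMeta(**header.get("meta", {}))
        events = []
        for lineno, obj in enumerate(parsed[1:], start=2):
            try:
                events.append(SessionEvent(**obj))
            except (TypeError, ValueError) as exc:
                raise SessionFormatError(f"{path}: invalid event on line {lineno}: {exc}") from exc
        return SessionRecord(geometry=geometry, config=config, meta=meta,
                             events=tuple(events))
    except SessionFormatError:
        raise
    except (TypeError, ValueError) as exc:
        raise SessionFormatError(f"{path}: invalid session: {exc}") from exc


# ---------------------------------------------------------------------------
# stroke extraction


def extract_strokes(record: SessionRecord) -> list[Stroke]:
    """Cut the event stream into strokes, attaching the active color/tool.

    Each stroke carries the color and tool most recently selected before its
    pen_down; before any selection the first configured palette color / tool
    apply (with a logged warning).  A stream that ends inside an open stroke
    is closed at its last pen sample, again with a warning.
    """
    strokes: list[Stroke] = []
    color = record.config.palette[0]
    tool = record.config.toolset[0]
    color_selected = tool_selected = False
    warned_default = False
    current: list[list[float]] | None = None
    cur_color = color
    cur_tool = tool
    for ev in record.events:
        if ev.kind == "select_color":
            color, color_selected = ev.color, True
        elif ev.kind == "select_tool":
            tool, tool_selected = ev.tool, True
        elif ev.kind == "pen_down":
            if not (color_selected and tool_selected) and not warned_default:
                warned_default = True
                logger.warning(
                    "stroke %d starts before an explicit %s selection; using default",
                    len(strokes),
                    "color" if not color_selected else "tool",
                )
            current = [[ev.t, ev.x, ev.y, ev.pressure]]
            cur_color, cur_tool = color, tool
        elif ev.kind in ("pen_move", "pen_up") and current is not None:
            sample = [ev.t, ev.x, ev.y, ev.pressure]
            if sample != current[-1]:  # drop exact duplicates (pen_up at rest)
                current.append(sample)
            if ev.kind == "pen_up":
                strokes.append(Stroke(np.array(current), cur_color, cur_tool))
                current = None
    if current is not None:
        logger.warning("event stream ends inside a stroke; closing at last sample")
        strokes.append(Stroke(np.array(current), cur_color, cur_tool))
    return strokes


def iter_pen_samples(record: SessionRecord) -> Iterator[tuple[int, SessionEvent]]:
    """Yield (index, event) for pen events, in stream order."""
    for i, ev in enumerate(record.events):
        if ev.kind in PEN_KINDS:
            yield i, ev
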