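"""Hierarchical/orthogonal statechart of the artwork, and its execution.

The artwork's construction process is modeled as a statechart: nested
states with exclusive (XOR) regions and orthogonal (AND) regions that are
simultaneously active.  The root ``ArtRoom`` toggles between
``ArtRoomSessionOff`` and ``ArtRoomSessionOn``; within an active session
the ``ArtWork`` runs concurrently with (stubbed) ``Client`` and
``ArtTherapist`` entities.  The artwork itself is exclusively ``Idle``,
``Materials_Selecting`` or ``Painting``; while ``Painting``, three
orthogonal components are live at once:

* ``Materials_Selected`` — which palette color and which tool the current
  stroke uses (one exclusive leaf per configured color / tool);
* ``Stroke_Characteristics`` — velocity {low, medium, high}, gradient
  (eight 45° compass sectors), pressure {low, medium, high} and running
  stroke size {short, medium, long};
* ``Page_Use`` — the page quarter (Q1..Q4) and the center/boundary part.

Executing the statechart over a session's event stream yields a
:class:`TimedTrace`: for every state (leaf and ancestor) the time intervals
during which it was active, annotated with the concrete driving value
(color name, cm/s, degrees, quarter id, ...).

Conventions
-----------
* Gradient angle = ``atan2(-Δy, Δx)`` in degrees on (−180, 180]; 0° points
  rightward, +90° up (screen y grows downward).  Compass sectors are 45°
  wide, centered on 0, ±45, ±90, ±135 and 180°; a boundary angle belongs
  to the counter-clockwise sector.
* Per-sample kinematics use the trailing two-sample window (current minus
  previous sample); the first sample of a stroke inherits the second's
  classification.  Each classification holds from its sample until the
  next one (left-sample hold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .session import SessionEvent, SessionRecord, StudioConfig

logger = logging.getLogger(__name__)

GRADIENT_SECTORS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
_SECTOR_BY_INDEX = {0: "E", 1: "NE", 2: "N", 3: "NW", 4: "W",
                    -4: "W", -3: "SW", -2: "S", -1: "SE"}

QUARTERS = ("Q1", "Q2", "Q3", "Q4")
PARTS = ("center", "boundary")
THREE_CLASSES = ("low", "medium", "high")
SIZE_CLASSES = ("short", "medium", "long")


class StatechartError(ValueError):
    """Event not legal in the current configuration."""


@dataclass
class StateNode:
    """A node of the state tree.

    ``mode`` describes how the node's children relate: ``"exclusive"``
    (exactly one child active while the node is active), ``"parallel"``
    (all children active), or ``"leaf"``.
    """

    name: str
    mode: str = "leaf"
    parent: Optional["StateNode"] = None
    children: list["StateNode"] = field(default_factory=list)

    def add(self, child: "StateNode") -> "StateNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self) -> Iterable["StateNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def find(self, name: str) -> "StateNode":
        for node in self.walk():
            if node.name == name:
                return node
        raise KeyError(name)

    def leaves(self) -> list["StateNode"]:
        return [n for n in self.walk() if not n.children]

    def __repr__(self) -> str:  # pragma: no cover
        return f"StateNode({self.name!r}, {self.mode}, {len(self.children)} children)"


def build_artwork_model(config: StudioConfig) -> StateNode:
    """Build the artwork state tree for a given studio configuration.

    The Color region gets one leaf per palette color, the Tool region one
    leaf per tool; kinematic and page regions are fixed.  ``Client`` and
    ``ArtTherapist`` are structural stubs: they are entered with the
    session but have no internal dynamics here.
    """
    root = StateNode("ArtRoom", "exclusive")
    root.add(StateNode("ArtRoomSessionOff"))
    on = root.add(StateNode("ArtRoomSessionOn", "parallel"))
    on.add(StateNode("Client"))
    on.add(StateNode("ArtTherapist"))
    artwork = on.add(StateNode("ArtWork", "exclusive"))
    artwork.add(StateNode("Idle"))
    artwork.add(StateNode("Materials_Selecting"))
    painting = artwork.add(StateNode("Painting", "parallel"))

    materials = painting.add(StateNode("Materials_Selected", "parallel"))
    color = materials.add(StateNode("Color", "exclusive"))
    for c in config.palette:
        color.add(StateNode(f"color:{c}"))
    tool = materials.add(StateNode("Tool", "exclusive"))
    for t in config.toolset:
        tool.add(StateNode(f"tool:{t}"))

    chars = painting.add(StateNode("Stroke_Characteristics", "parallel"))
    for region, classes in (("Velocity", THREE_CLASSES),
                            ("Pressure", THREE_CLASSES),
                            ("Size", SIZE_CLASSES)):
        node = chars.add(StateNode(region, "exclusive"))
        for cls in classes:
            node.add(StateNode(f"{region.lower()}:{cls}"))
    gradient = chars.add(StateNode("Gradient", "exclusive"))
    for s in GRADIENT_SECTORS:
        gradient.add(StateNode(f"gradient:{s}"))

    page = painting.add(StateNode("Page_Use", "parallel"))
    quarters = page.add(StateNode("Quarters", "exclusive"))
    for q in QUARTERS:
        quarters.add(StateNode(f"quarter:{q}"))
    parts = page.add(StateNode("Parts", "exclusive"))
    for p in PARTS:
        parts.add(StateNode(f"part:{p}"))
    return root


# ---------------------------------------------------------------------------
# classification helpers


def gradient_angle(dx: float, dy: float) -> float:
    """Direction of motion in degrees on (−180, 180]; 0°=right, +90°=up."""
    ang = math.degrees(math.atan2(-dy, dx))
    if ang <= -180.0:
        ang += 360.0
    return ang


def gradient_sector(angle_deg: float) -> str:
    """Map an angle to its 45° compass sector (ties go counter-clockwise)."""
    idx = math.floor(angle_deg / 45.0 + 0.5)
    return _SECTOR_BY_INDEX[idx]


def three_class(value: float, thresholds: tuple[float, float],
                labels: tuple[str, str, str] = THREE_CLASSES) -> str:
    lo, hi = thresholds
    if value < lo:
        return labels[0]
    if value > hi:
        return labels[2]
    return labels[1]


# ---------------------------------------------------------------------------
# configuration & trace


def validate_configuration(root: StateNode, active: frozenset[str]) -> None:
    """Raise if ``active`` is not root-closed and region-consistent."""
    if root.name not in active:
        raise StatechartError("root must always be active")
    for node in root.walk():
        if node.name not in active:
            for child in node.walk():
                if child is not node and child.name in active:
                    raise StatechartError(
                        f"{child.name} active while ancestor {node.name} is not")
            continue
        if node.mode == "exclusive":
            n_active = sum(1 for c in node.children if c.name in active)
            if n_active != 1:
                raise StatechartError(
                    f"exclusive region {node.name} has {n_active} active children")
        elif node.mode == "parallel":
            missing = [c.name for c in node.children if c.name not in active]
            if missing:
                raise StatechartError(
                    f"orthogonal region {node.name} missing children {missing}")


@dataclass(frozen=True)
class Interval:
    """Occupancy of one state over [t_start, t_end)."""

    state: str
    t_start: float
    t_end: float
    annotation: object = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TimedTrace:
    """Statechart occupancy intervals for one session."""

    t_start: float
    t_end: float
    intervals: list[Interval]

    def intervals_for(self, state: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.state == state]

    def occupancy(self, state: str) -> float:
        """Total time the state was active (seconds)."""
        return sum(iv.duration for iv in self.intervals if iv.state == state)

    def leaf_intervals(self, prefix: str) -> list[Interval]:
        """Intervals of all leaves named ``prefix:<value>``, time-ordered."""
        out = [iv for iv in self.intervals if iv.state.startswith(prefix + ":")]
        out.sort(key=lambda iv: (iv.t_start, iv.t_end))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for iv in sorted(self.intervals, key=lambda iv: (iv.t_start, iv.state)):
            state = iv.state
            region, _, value = state.partition(":")
            rows.append({"region": region if value else "",
                         "state": state, "t_start": iv.t_start,
                         "t_end": iv.t_end, "annotation": iv.annotation})
        return pd.DataFrame(rows, columns=["region", "state", "t_start",
                                           "t_end", "annotation"])


# ---------------------------------------------------------------------------
# the tracker


def _active_set(config: StudioConfig, session_on: bool,
                artwork_child: str | None,
                leaves: dict[str, str] | None) -> frozenset[str]:
    if not session_on:
        return frozenset({"ArtRoom", "ArtRoomSessionOff"})
    active = {"ArtRoom", "ArtRoomSessionOn", "Client", "ArtTherapist", "ArtWork",
              artwork_child}
    if artwork_child == "Painting":
        active |= {"Materials_Selected", "Color", "Tool",
                   "Stroke_Characteristics", "Velocity", "Gradient",
                   "Pressure", "Size", "Page_Use", "Quarters", "Parts"}
        active |= set(leaves.values())
    return frozenset(active)


class ArtworkTracker:
    """Steps the artwork statechart over session events.

    Holds the pending material selections and the trailing pen sample so
    that stroke-characteristic leaves can be (re)classified on every pen
    event.  :meth:`step` mutates the tracker and returns the new
    configuration (a frozenset of active state names).
    """

    def __init__(self, record: SessionRecord):
        self.record = record
        self.config = record.config
        self.geometry = record.geometry
        self.model = build_artwork_model(record.config)
        self.session_on = False
        self.artwork_child: str | None = None
        self.pending_color = record.config.palette[0]
        self.pending_tool = record.config.toolset[0]
        self._stroke_color = self.pending_color
        self._stroke_tool = self.pending_tool
        self.leaves: dict[str, str] = {}
        self.annotations: dict[str, object] = {}
        self._prev_sample: tuple[float, float, float] | None = None  # t, x, y
        self._prev_velocity = 0.0
        self._prev_angle = 0.0
        self._stroke_length = 0.0
        self.configuration = _active_set(self.config, False, None, None)

    # -- classification ----------------------------------------------------

    def _classify(self, ev: SessionEvent, velocity: float, angle: float) -> None:
        cfg = self.config
        self.leaves = {
            "color": f"color:{self._stroke_color}",
            "tool": f"tool:{self._stroke_tool}",
            "velocity": f"velocity:{three_class(velocity, cfg.velocity_thresholds)}",
            "gradient": f"gradient:{gradient_sector(angle)}",
            "pressure": f"pressure:{three_class(ev.pressure, cfg.pressure_thresholds)}",
            "size": f"size:{three_class(self._stroke_length, cfg.size_thresholds, SIZE_CLASSES)}",
            "quarter": f"quarter:{self.geometry.quarter(ev.x, ev.y)}",
            "part": f"part:{self.geometry.part(ev.x, ev.y)}",
        }
        self.annotations = {
            self.leaves["color"]: self._stroke_color,
            self.leaves["tool"]: self._stroke_tool,
            self.leaves["velocity"]: velocity,
            self.leaves["gradient"]: angle,
            self.leaves["pressure"]: ev.pressure,
            self.leaves["size"]: self._stroke_length,
            self.leaves["quarter"]: self.geometry.quarter(ev.x, ev.y),
            self.leaves["part"]: self.geometry.part(ev.x, ev.y),
        }

    def _window(self, ev: SessionEvent) -> tuple[float, float]:
        """Velocity (cm/s) and gradient angle of the trailing window."""
        if self._prev_sample is None:
            return 0.0, 0.0
        t0, x0, y0 = self._prev_sample
        dt = ev.t - t0
        dx, dy = ev.x - x0, ev.y - y0
        dist = math.hypot(dx, dy)
        self._stroke_length += dist
        velocity = dist / dt if dt > 0 else self._prev_velocity
        angle = gradient_angle(dx, dy) if dist > 0 else self._prev_angle
        self._prev_velocity, self._prev_angle = velocity, angle
        return velocity, angle

    # -- stepping ----------------------------------------------------------

    def step(self, ev: SessionEvent,
             context: tuple[float, float] | None = None) -> frozenset[str]:
        """Consume one event; ``context`` optionally supplies the (velocity,
        gradient angle) the entering stroke sample should inherit (used to
        give a stroke's first sample its second sample's classification)."""
        if not self.session_on:
            if ev.kind != "session_start":
                raise StatechartError(
                    f"event {ev.kind} while ArtRoomSessionOff")
            self.session_on = True
            self.artwork_child = "Idle"
        elif ev.kind == "session_start":
            raise StatechartError("duplicate session_start")
        elif ev.kind == "session_end":
            if self.artwork_child == "Painting":
                raise StatechartError("session_end inside a stroke")
            self.session_on = False
            self.artwork_child = None
        elif ev.kind == "select_color":
            self.pending_color = ev.color
            if self.artwork_child != "Painting":
                self.artwork_child = "Materials_Selecting"
        elif ev.kind == "select_tool":
            self.pending_tool = ev.tool
            if self.artwork_child != "Painting":
                self.artwork_child = "Materials_Selecting"
        elif ev.kind == "pen_down":
            self.artwork_child = "Painting"
            self._stroke_color = self.pending_color
            self._stroke_tool = self.pending_tool
            self._stroke_length = 0.0
            self._prev_velocity = self._prev_angle = 0.0
            self._prev_sample = None
            velocity, angle = context if context is not None else (0.0, 0.0)
            self._prev_velocity, self._prev_angle = velocity, angle
            self._classify(ev, velocity, angle)
            self._prev_sample = (ev.t, ev.x, ev.y)
        elif ev.kind == "pen_move":
            if self.artwork_child == "Painting":
                velocity, angle = self._window(ev)
                self._classify(ev, velocity, angle)
                self._prev_sample = (ev.t, ev.x, ev.y)
        elif ev.kind == "pen_up":
            if self.artwork_child == "Painting":
                self._window(ev)  # advance kinematics; no interval follows
                self.artwork_child = "Idle"
                self._prev_sample = None
        self.configuration = _active_set(
            self.config, self.session_on, self.artwork_child,
            self.leaves if self.artwork_child == "Painting" else None)
        return self.configuration


def _stroke_entry_context(record: SessionRecord, i: int) -> tuple[float, float]:
    """Velocity/angle of the segment from a pen_down to its next pen sample."""
    ev = record.events[i]
    for nxt in record.events[i + 1:]:
        if nxt.kind in ("pen_move", "pen_up"):
            dt = nxt.t - ev.t
            dx, dy = nxt.x - ev.x, nxt.y - ev.y
            dist = math.hypot(dx, dy)
            if dist == 0:
                return 0.0, 0.0
            return (dist / dt if dt > 0 else 0.0), gradient_angle(dx, dy)
        if nxt.kind not in ("select_color", "select_tool"):
            break
    return 0.0, 0.0


def run(record: SessionRecord, validate: bool = False) -> TimedTrace:
    """Execute the statechart over all events and emit the timed trace.

    The trace contains one interval per maximal span over which a state was
    continuously active; zero-duration occupancies are dropped.  With
    ``validate=True`` every intermediate configuration is checked for
    region consistency (used by the test suite).
    """
    tracker = ArtworkTracker(record)
    events = record.events
    if not events:
        return TimedTrace(0.0, 0.0, [])
    t_end = record.t_end
    if events[-1].kind != "session_end":
        logger.warning("session has no session_end; closing trace at last event")
    intervals: list[Interval] = []
    open_at: dict[str, tuple[float, object]] = {}

    def _sync(t: float) -> None:
        active = tracker.configuration
        for name in list(open_at):
            if name not in active:
                t0, ann = open_at.pop(name)
                if t > t0:
                    intervals.append(Interval(name, t0, t, ann))
        for name in active:
            if name not in open_at:
                open_at[name] = (t, tracker.annotations.get(name))

    # the session exists from t=0 in SessionOff until session_start
    _sync(events[0].t)
    for i, ev in enumerate(events):
        context = _stroke_entry_context(record, i) if ev.kind == "pen_down" else None
        tracker.step(ev, context=context)
        if validate:
            validate_configuration(tracker.model, tracker.configuration)
        _sync(ev.t)
    for name, (t0, ann) in open_at.items():
        if t_end > t0:
            intervals.append(Interval(name, t0, t_end, ann))
    return TimedTrace(events[0].t, t_end, intervals)
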