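"""Per-session parameter/metric table of the artwork construction process.

Everything here is derived from the five raw channels (x, y, pressure,
color choice, tool choice).  The table covers:

* session timing — total duration, net drawing vs idle time, material-
  selection time;
* stroke kinematics — count, total/average length, average velocity
  (total length over in-stroke time), duration-weighted average pressure,
  length-weighted circular average drawing direction, strokes per second;
* material usage — time per color and per tool (as % of drawing time),
  erase time, fraction of palette/toolset actually used, switch counts;
* page use — time per quarter and center/boundary, swept area coverage,
  midline crossovers within strokes, and "stroke start crossovers" (a new
  stroke beginning in a quarter edge-adjacent to where the hand last was).

Two computation paths exist for the occupancy metrics: from the statechart
:class:`~atelier.statechart.TimedTrace` (the primary path used by
:func:`compute_metrics`) and directly from the strokes/events
(:func:`stroke_occupancy_metrics`); the two agree to float precision and
are cross-checked in the test suite.

Accounting conventions (see docs/methods.md): eraser strokes count fully in
stroke/kinematic metrics; their time is reported under the pseudo-color
``"erase"`` and excluded from real-color occupancy.  State-time weighting
is left-sample hold: each pen sample's classification holds until the next
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .session import (
    ERASE_PSEUDO_COLOR,
    PageGeometry,
    SessionRecord,
    Stroke,
    StudioConfig,
    extract_strokes,
)
from .statechart import Interval, TimedTrace, run as run_statechart

QUARTER_ADJACENCY = {
    "Q1": frozenset({"Q2", "Q3"}),
    "Q2": frozenset({"Q1", "Q4"}),
    "Q3": frozenset({"Q1", "Q4"}),
    "Q4": frozenset({"Q2", "Q3"}),
}

#: Scalar fields of MetricsTable scanned by the cohort analysis.
SCALAR_METRICS = (
    "session_duration", "drawing_time", "drawing_pct", "idle_pct",
    "selecting_time", "stroke_count", "total_stroke_length",
    "avg_stroke_length", "avg_velocity", "avg_pressure", "avg_gradient",
    "strokes_per_second", "color_switches", "tool_switches",
    "switches_per_color", "colors_used_pct", "tools_used_pct",
    "erase_time_pct", "area_used_pct", "center_pct", "boundary_pct",
    "stroke_start_crossovers", "stroke_crossovers_h", "stroke_crossovers_v",
    "first_stroke_in_center",
)


@dataclass
class MetricsTable:
    """All per-session parameters/metrics, plus cross-sections."""

    session_duration: float
    drawing_time: float
    drawing_pct: float
    idle_pct: float
    selecting_time: float
    stroke_count: int
    total_stroke_length: float
    avg_stroke_length: float
    avg_velocity: float
    avg_pressure: float
    avg_gradient: float
    strokes_per_second: float
    color_switches: int
    tool_switches: int
    switches_per_color: float
    colors_used_pct: float
    tools_used_pct: float
    erase_time_pct: float
    area_used_pct: float
    center_pct: float
    boundary_pct: float
    stroke_start_crossovers: int
    stroke_crossovers_h: int
    stroke_crossovers_v: int
    first_stroke_in_center: bool
    color_time: dict[str, float] = field(default_factory=dict)
    color_pct: dict[str, float] = field(default_factory=dict)
    tool_time: dict[str, float] = field(default_factory=dict)
    tool_pct: dict[str, float] = field(default_factory=dict)
    quarter_time: dict[str, float] = field(default_factory=dict)
    quarter_pct: dict[str, float] = field(default_factory=dict)
    cross_sections: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False
    palette: tuple[str, ...] = ()
    toolset: tuple[str, ...] = ()

    def flatten(self) -> dict[str, float]:
        """Flat numeric view (dict fields expanded) for frames and scans."""
        out: dict[str, float] = {}
        for name in SCALAR_METRICS:
            out[name] = float(getattr(self, name))
        for color in (*self.palette, ERASE_PSEUDO_COLOR):
            out[f"color_pct:{color}"] = self.color_pct.get(color, 0.0)
        for tool in self.toolset:
            out[f"tool_pct:{tool}"] = self.tool_pct.get(tool, 0.0)
        for q in ("Q1", "Q2", "Q3", "Q4"):
            out[f"quarter_pct:{q}"] = self.quarter_pct.get(q, 0.0)
        return out


# ---------------------------------------------------------------------------
# kinematics


def stroke_length(stroke: Stroke) -> float:
    """Polyline length of a stroke in cm (0 for a single-sample stroke)."""
    return stroke.length()


@dataclass(frozen=True)
class Kinematics:
    total_stroke_length: float
    avg_velocity: float
    avg_pressure: float
    avg_gradient: float
    avg_stroke_length: float
    strokes_per_second: float
    drawing_time: float
    degenerate: bool


def session_kinematics(strokes: Sequence[Stroke]) -> Kinematics:
    """Aggregate stroke kinematics for a session.

    avg_velocity is total length over total in-stroke time; avg_pressure
    is the left-hold time-weighted mean of sample pressures; avg_gradient
    is the length-weighted circular mean of segment directions, which
    reduces to the direction of the summed stroke displacement vectors.
    Degenerate sessions (no positive in-stroke time) report zeros.
    """
    if not strokes:
        return Kinematics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True)
    total_length = 0.0
    drawing_time = 0.0
    weighted_pressure = 0.0
    disp = np.zeros(2)
    for s in strokes:
        total_length += s.length()
        drawing_time += s.duration
        if len(s) >= 2:
            dt = np.diff(s.samples[:, 0])
            weighted_pressure += float(np.sum(s.samples[:-1, 3] * dt))
            disp += s.xy[-1] - s.xy[0]
    degenerate = drawing_time <= 0.0
    if degenerate:
        return Kinematics(total_length, 0.0, 0.0, 0.0,
                          total_length / len(strokes), 0.0, 0.0, True)
    if np.hypot(*disp) > 0:
        avg_gradient = math.degrees(math.atan2(-disp[1], disp[0]))
        if avg_gradient <= -180.0:
            avg_gradient += 360.0
    else:
        avg_gradient = 0.0
    return Kinematics(
        total_stroke_length=total_length,
        avg_velocity=total_length / drawing_time,
        avg_pressure=weighted_pressure / drawing_time,
        avg_gradient=avg_gradient,
        avg_stroke_length=total_length / len(strokes),
        strokes_per_second=len(strokes) / drawing_time,
        drawing_time=drawing_time,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# occupancy (trace path and direct stroke path)


@dataclass(frozen=True)
class Occupancy:
    session_duration: float
    drawing_time: float
    selecting_time: float
    drawing_pct: float
    idle_pct: float
    color_time: dict[str, float]
    tool_time: dict[str, float]
    quarter_time: dict[str, float]
    part_time: dict[str, float]
    cross_sections: dict[tuple[str, str], float]
    erase_time_pct: float
    degenerate: bool

    def pct_of_drawing(self, times: Mapping[str, float]) -> dict[str, float]:
        if self.drawing_time <= 0:
            return {k: 0.0 for k in times}
        return {k: v / self.drawing_time * 100.0 for k, v in times.items()}


def _joint_intervals(a: list[Interval], b: list[Interval]):
    """Intersect two sorted interval partitions; yields (lo, hi, val_a, val_b)."""
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].t_start, b[j].t_start)
        hi = min(a[i].t_end, b[j].t_end)
        if hi > lo:
            yield lo, hi, a[i].state.split(":", 1)[1], b[j].state.split(":", 1)[1]
        if a[i].t_end <= b[j].t_end:
            i += 1
        else:
            j += 1


def _assemble_occupancy(session_duration: float, painting: float,
                        selecting: float, joint, quarter_items, part_items
                        ) -> Occupancy:
    color_time: dict[str, float] = {}
    tool_time: dict[str, float] = {}
    cross: dict[tuple[str, str], float] = {}
    for dur, color, tool in joint:
        tool_time[tool] = tool_time.get(tool, 0.0) + dur
        key = ERASE_PSEUDO_COLOR if tool == "eraser" else color
        color_time[key] = color_time.get(key, 0.0) + dur
        cross[(color, tool)] = cross.get((color, tool), 0.0) + dur
    quarter_time: dict[str, float] = {}
    for dur, q in quarter_items:
        quarter_time[q] = quarter_time.get(q, 0.0) + dur
    part_time: dict[str, float] = {}
    for dur, p in part_items:
        part_time[p] = part_time.get(p, 0.0) + dur
    degenerate = painting <= 0.0
    drawing_pct = painting / session_duration * 100.0 if session_duration > 0 else 0.0
    return Occupancy(
        session_duration=session_duration,
        drawing_time=painting,
        selecting_time=selecting,
        drawing_pct=drawing_pct,
        idle_pct=100.0 - drawing_pct,
        color_time=color_time,
        tool_time=tool_time,
        quarter_time=quarter_time,
        part_time=part_time,
        cross_sections=cross,
        erase_time_pct=(tool_time.get("eraser", 0.0) / painting * 100.0
                        if painting > 0 else 0.0),
        degenerate=degenerate,
    )


def occupancy_metrics(trace: TimedTrace,
                      strokes: Sequence[Stroke] | None = None) -> Occupancy:
    """Occupancy split computed from the statechart trace.

    ``drawing_pct`` is Painting occupancy over session duration;
    ``idle_pct`` is its complement (Materials_Selecting time is reported
    separately but folds into idle for the two-way split).  Per-color/tool/
    quarter values are occupancies of the corresponding leaves.
    """
    session_duration = trace.t_end - trace.t_start
    painting = trace.occupancy("Painting")
    selecting = trace.occupancy("Materials_Selecting")
    joint = [(hi - lo, c, t) for lo, hi, c, t in
             _joint_intervals(trace.leaf_intervals("color"),
                              trace.leaf_intervals("tool"))]
    quarters = [(iv.duration, iv.state.split(":", 1)[1])
                for iv in trace.leaf_intervals("quarter")]
    parts = [(iv.duration, iv.state.split(":", 1)[1])
             for iv in trace.leaf_intervals("part")]
    return _assemble_occupancy(session_duration, painting, selecting,
                               joint, quarters, parts)


def stroke_occupancy_metrics(record: SessionRecord,
                             strokes: Sequence[Stroke] | None = None) -> Occupancy:
    """Occupancy split recomputed directly from strokes and events.

    Independent of the statechart engine; agrees with
    :func:`occupancy_metrics` to float precision.
    """
    if strokes is None:
        strokes = extract_strokes(record)
    geometry = record.geometry
    session_duration = record.duration
    painting = sum(s.duration for s in strokes)
    # selection time: from the first selection event in an out-of-stroke gap
    # until the next pen_down (or end of session)
    selecting = 0.0
    sel_start: float | None = None
    in_stroke = False
    for ev in record.events:
        if ev.kind == "pen_down":
            in_stroke = True
            if sel_start is not None:
                selecting += ev.t - sel_start
                sel_start = None
        elif ev.kind == "pen_up":
            in_stroke = False
        elif ev.kind in ("select_color", "select_tool"):
            if not in_stroke and sel_start is None:
                sel_start = ev.t
        elif ev.kind == "session_end" and sel_start is not None:
            selecting += ev.t - sel_start
            sel_start = None
    if sel_start is not None:
        selecting += record.t_end - sel_start
    joint = [(s.duration, s.color, s.tool) for s in strokes]
    quarter_items: list[tuple[float, str]] = []
    part_items: list[tuple[float, str]] = []
    for s in strokes:
        dts = np.diff(s.samples[:, 0])
        for i, dt in enumerate(dts):
            x, y = s.samples[i, 1], s.samples[i, 2]
            quarter_items.append((float(dt), geometry.quarter(x, y)))
            part_items.append((float(dt), geometry.part(x, y)))
    return _assemble_occupancy(session_duration, painting, selecting,
                               joint, quarter_items, part_items)


# ---------------------------------------------------------------------------
# switches


@dataclass(frozen=True)
class SwitchCounts:
    color_switches: int
    tool_switches: int
    switches_per_color: float
    colors_used_pct: float
    tools_used_pct: float
    colors_used: frozenset[str]
    tools_used: frozenset[str]


def switch_counts(strokes: Sequence[Stroke], config: StudioConfig) -> SwitchCounts:
    """Count color/tool changes between consecutive strokes.

    Distinct colors used (and colors_used_pct) exclude eraser strokes,
    whose "color" is the eraser itself; switch counts run over the raw
    per-stroke color/tool sequences.
    """
    colors = [s.color for s in strokes]
    tools = [s.tool for s in strokes]
    color_switches = sum(1 for a, b in zip(colors, colors[1:]) if a != b)
    tool_switches = sum(1 for a, b in zip(tools, tools[1:]) if a != b)
    colors_used = frozenset(s.color for s in strokes if s.tool != "eraser")
    tools_used = frozenset(tools)
    return SwitchCounts(
        color_switches=color_switches,
        tool_switches=tool_switches,
        switches_per_color=(color_switches / len(colors_used)
                            if colors_used else 0.0),
        colors_used_pct=len(colors_used) / len(config.palette) * 100.0,
        tools_used_pct=len(tools_used) / len(config.toolset) * 100.0,
        colors_used=colors_used,
        tools_used=tools_used,
    )


# ---------------------------------------------------------------------------
# page geometry


def coverage_mask(strokes: Sequence[Stroke], geometry: PageGeometry,
                  config: StudioConfig,
                  cell: float | None = None) -> np.ndarray:
    """Boolean raster of page cells swept by any stroke.

    Each stroke sweeps a disc of half its tool's nominal width along its
    polyline; a cell counts as covered when its center lies within the
    sweep.  Eraser strokes cover cells like any other tool (they are page
    activity), regardless of what they removed.
    """
    if cell is None:
        cell = config.raster_cell
    nx = max(1, int(math.ceil(geometry.width / cell)))
    ny = max(1, int(math.ceil(geometry.height / cell)))
    mask = np.zeros((ny, nx), dtype=bool)
    xs = (np.arange(nx) + 0.5) * cell
    ys = (np.arange(ny) + 0.5) * cell
    for s in strokes:
        r = config.tool_width(s.tool) / 2.0
        pts = s.xy
        segs = zip(pts[:-1], pts[1:]) if len(pts) > 1 else [(pts[0], pts[0])]
        for p0, p1 in segs:
            x_lo, x_hi = sorted((p0[0], p1[0]))
            y_lo, y_hi = sorted((p0[1], p1[1]))
            j0 = max(0, int((x_lo - r) / cell))
            j1 = min(nx, int(math.ceil((x_hi + r) / cell)) + 1)
            i0 = max(0, int((y_lo - r) / cell))
            i1 = min(ny, int(math.ceil((y_hi + r) / cell)) + 1)
            if j0 >= j1 or i0 >= i1:
                continue
            gx = xs[j0:j1][None, :]
            gy = ys[i0:i1][:, None]
            vx, vy = p1[0] - p0[0], p1[1] - p0[1]
            denom = vx * vx + vy * vy
            if denom == 0:
                d2 = (gx - p0[0]) ** 2 + (gy - p0[1]) ** 2
            else:
                t = ((gx - p0[0]) * vx + (gy - p0[1]) * vy) / denom
                t = np.clip(t, 0.0, 1.0)
                d2 = (gx - (p0[0] + t * vx)) ** 2 + (gy - (p0[1] + t * vy)) ** 2
            mask[i0:i1, j0:j1] |= d2 <= r * r
    return mask


@dataclass(frozen=True)
class PageUse:
    sample_quarters: list[list[str]]
    sample_parts: list[list[str]]
    area_used_pct: float
    stroke_start_crossovers: int
    stroke_crossovers_h: int
    stroke_crossovers_v: int
    first_stroke_in_center: bool


def page_geometry_metrics(strokes: Sequence[Stroke], geometry: PageGeometry,
                          config: StudioConfig) -> PageUse:
    """Spatial page-use metrics.

    Crossover naming: a "horizontal" crossover crosses the *horizontal*
    midline (moving between vertically adjacent quarters), a "vertical"
    one crosses the vertical midline; a sample pair crossing both at once
    increments both counters.  Stroke-start crossovers compare a stroke's
    first-sample quarter against the previous stroke's last-sample quarter
    and count edge adjacency only (diagonal quarters are not adjacent).
    """
    half_w, half_h = geometry.width / 2.0, geometry.height / 2.0
    sample_quarters: list[list[str]] = []
    sample_parts: list[list[str]] = []
    crossovers_h = crossovers_v = 0
    start_crossovers = 0
    prev_end_quarter: str | None = None
    for s in strokes:
        qs = [geometry.quarter(x, y) for x, y in s.xy]
        ps = [geometry.part(x, y) for x, y in s.xy]
        sample_quarters.append(qs)
        sample_parts.append(ps)
        top = s.xy[:, 1] <= half_h
        left = s.xy[:, 0] <= half_w
        crossovers_h += int(np.sum(top[1:] != top[:-1]))
        crossovers_v += int(np.sum(left[1:] != left[:-1]))
        if prev_end_quarter is not None and qs[0] in QUARTER_ADJACENCY[prev_end_quarter]:
            start_crossovers += 1
        prev_end_quarter = qs[-1]
    area_used_pct = float(coverage_mask(strokes, geometry, config).mean()) * 100.0
    first_in_center = bool(strokes) and sample_parts[0][0] == "center"
    return PageUse(
        sample_quarters=sample_quarters,
        sample_parts=sample_parts,
        area_used_pct=area_used_pct,
        stroke_start_crossovers=start_crossovers,
        stroke_crossovers_h=crossovers_h,
        stroke_crossovers_v=crossovers_v,
        first_stroke_in_center=first_in_center,
    )


# ---------------------------------------------------------------------------
# assembly


def compute_metrics(record: SessionRecord,
                    trace: Optional[TimedTrace] = None,
                    use_trace: bool = True) -> MetricsTable:
    """Compute the full metrics table for one session.

    By default the occupancy split comes from executing the statechart
    (``use_trace=True``); with ``use_trace=False`` the direct stroke path
    is used instead (identical values, cheaper — used for large cohort
    simulations).
    """
    strokes = extract_strokes(record)
    if use_trace:
        if trace is None:
            trace = run_statechart(record)
        occ = occupancy_metrics(trace, strokes)
    else:
        occ = stroke_occupancy_metrics(record, strokes)
    kin = session_kinematics(strokes)
    sw = switch_counts(strokes, record.config)
    page = page_geometry_metrics(strokes, record.geometry, record.config)
    color_pct = occ.pct_of_drawing(occ.color_time)
    tool_pct = occ.pct_of_drawing(occ.tool_time)
    quarter_pct = occ.pct_of_drawing(occ.quarter_time)
    part_pct = occ.pct_of_drawing(occ.part_time)
    return MetricsTable(
        session_duration=occ.session_duration,
        drawing_time=occ.drawing_time,
        drawing_pct=occ.drawing_pct,
        idle_pct=occ.idle_pct,
        selecting_time=occ.selecting_time,
        stroke_count=len(strokes),
        total_stroke_length=kin.total_stroke_length,
        avg_stroke_length=kin.avg_stroke_length,
        avg_velocity=kin.avg_velocity,
        avg_pressure=kin.avg_pressure,
        avg_gradient=kin.avg_gradient,
        strokes_per_second=kin.strokes_per_second,
        color_switches=sw.color_switches,
        tool_switches=sw.tool_switches,
        switches_per_color=sw.switches_per_color,
        colors_used_pct=sw.colors_used_pct,
        tools_used_pct=sw.tools_used_pct,
        erase_time_pct=occ.erase_time_pct,
        area_used_pct=page.area_used_pct,
        center_pct=part_pct.get("center", 0.0),
        boundary_pct=part_pct.get("boundary", 0.0),
        stroke_start_crossovers=page.stroke_start_crossovers,
        stroke_crossovers_h=page.stroke_crossovers_h,
        stroke_crossovers_v=page.stroke_crossovers_v,
        first_stroke_in_center=page.first_stroke_in_center,
        color_time=occ.color_time,
        color_pct=color_pct,
        tool_time=occ.tool_time,
        tool_pct=tool_pct,
        quarter_time=occ.quarter_time,
        quarter_pct=quarter_pct,
        cross_sections=occ.cross_sections,
        degenerate=occ.degenerate or kin.degenerate,
        palette=record.config.palette,
        toolset=record.config.toolset,
    )


def compare_sessions(a: MetricsTable, b: MetricsTable) -> pd.DataFrame:
    """Side-by-side comparison of two sessions' metric tables.

    One row per flattened metric with columns a, b, difference (a − b)
    and ratio (a / b, NaN where b is 0).  Both tables must come from the
    same studio configuration.
    """
    if a.palette != b.palette or a.toolset != b.toolset:
        raise ValueError("cannot compare sessions with different studio configs")
    fa, fb = a.flatten(), b.flatten()
    rows = []
    for name in fa:
        va, vb = fa[name], fb[name]
        rows.append({
            "metric": name, "a": va, "b": vb, "difference": va - vb,
            "ratio": va / vb if vb != 0 else float("nan"),
        })
    return pd.DataFrame(rows).set_index("metric")


def metrics_to_frame(tables: Mapping[str, MetricsTable]) -> pd.DataFrame:
    """Stack flattened metric tables into a DataFrame (one row per key)."""
    return pd.DataFrame({k: t.flatten() for k, t in tables.items()}).T
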