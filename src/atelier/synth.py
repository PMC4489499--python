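"""Synthetic drawing sessions with known ground truth.

Scripted sessions are built from geometric stroke primitives (line,
polyline, circle arc, zigzag) drawn at constant speed with a constant or
linearly ramping pressure profile, separated by idle gaps and optional
material-selection events.  :func:`realize_scripts` samples each primitive
along its arc length at a fixed rate and emits a valid
:class:`~atelier.session.SessionRecord`; alongside it,
:func:`script_ground_truth` computes the session's expected metrics table
analytically from the script parameters — positions on the sampling grid
come from the primitives' closed-form arc-length parametrization, never
from the realized event stream — so the full decoding pipeline can be
checked against an independent oracle.

:func:`generate_cohort` draws whole cohorts of random sessions from
per-group distributions (stroke count, speed, color preference, erase
propensity, idle fraction, pressure), deterministic given the spec's seed,
for calibration and power studies of the cohort statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .session import (
    DEFAULT_PALETTE,
    DEFAULT_TOOLSET,
    ERASE_PSEUDO_COLOR,
    PageGeometry,
    SessionEvent,
    SessionMeta,
    SessionRecord,
    StudioConfig,
)

Primitive = Literal["line", "polyline", "circle_arc", "zigzag"]


@dataclass(frozen=True)
class StrokeScript:
    """One scripted stroke: geometry + speed + pressure + materials.

    ``points`` are the control vertices for line/polyline/zigzag (cm); a
    zigzag oscillates perpendicular to the points[0]→points[1] axis with
    the given amplitude and cycle count.  ``circle_arc`` uses center,
    radius and angles in degrees (math convention on a y-down page, so
    increasing angle sweeps counter-clockwise on screen).  ``pressure``
    is either a constant or a (start, end) linear ramp.  ``pre_gap`` is
    idle/selection time before the pen touches the page.
    """

    primitive: Primitive
    color: str = DEFAULT_PALETTE[0]
    tool: str = DEFAULT_TOOLSET[0]
    speed: float = 5.0  # cm/s
    pressure: float | tuple[float, float] = 0.5
    pre_gap: float = 1.0
    select: bool = True
    points: tuple[tuple[float, float], ...] = ()
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.0
    theta0: float = 0.0
    theta1: float = 360.0
    amplitude: float = 1.0
    cycles: int = 3

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be positive")

    # -- geometry ----------------------------------------------------------

    def vertices(self) -> np.ndarray:
        """Control polyline (for circle arcs: None — use point_at)."""
        if self.primitive in ("line", "polyline"):
            pts = np.asarray(self.points, dtype=float)
            if len(pts) < 1:
                raise ValueError("line/polyline needs control points")
            return pts
        if self.primitive == "zigzag":
            p0 = np.asarray(self.points[0], dtype=float)
            p1 = np.asarray(self.points[1], dtype=float)
            axis = p1 - p0
            norm = np.hypot(*axis)
            if norm == 0:
                raise ValueError("zigzag needs distinct endpoints")
            perp = np.array([-axis[1], axis[0]]) / norm
            n = 2 * self.cycles
            verts = [p0]
            for j in range(1, n):
                u = j / n
                off = self.amplitude if j % 2 == 1 else -self.amplitude
                verts.append(p0 + axis * u + perp * off)
            verts.append(p1)
            return np.asarray(verts)
        raise ValueError(f"{self.primitive} has no vertex form")

    def length(self) -> float:
        """Exact arc length (cm)."""
        if self.primitive == "circle_arc":
            return self.radius * abs(math.radians(self.theta1 - self.theta0))
        pts = self.vertices()
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Exact position(s) at arc length ``s`` from the start; (n, 2)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.primitive == "circle_arc":
            sign = 1.0 if self.theta1 >= self.theta0 else -1.0
            theta = math.radians(self.theta0) + sign * s / self.radius
            cx, cy = self.center
            return np.column_stack([cx + self.radius * np.cos(theta),
                                    cy - self.radius * np.sin(theta)])
        pts = self.vertices()
        if len(pts) < 2:
            return np.repeat(pts[:1], len(s), axis=0)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.clip(s, 0.0, cum[-1])
        return np.column_stack([np.interp(s, cum, pts[:, 0]),
                                np.interp(s, cum, pts[:, 1])])

    def duration(self) -> float:
        return self.length() / self.speed

    def pressure_profile(self, frac: np.ndarray) -> np.ndarray:
        frac = np.asarray(frac, dtype=float)
        if isinstance(self.pressure, tuple):
            p0, p1 = self.pressure
            return p0 + (p1 - p0) * frac
        return np.full_like(frac, float(self.pressure))

    def sample_times(self, sample_rate: float) -> np.ndarray:
        """Relative sample times: uniform at ``sample_rate`` plus the
        control-vertex passage times (endpoints always included), so a
        polyline's sampled chords sum to its exact length."""
        dur = self.duration()
        if dur <= 0:
            return np.array([0.0])
        n = max(1, int(math.ceil(dur * sample_rate)))
        times = np.linspace(0.0, dur, n + 1)
        if self.primitive != "circle_arc":
            pts = self.vertices()
            if len(pts) > 2:
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                vertex_times = np.cumsum(seg)[:-1] / self.speed
                times = np.sort(np.concatenate([times, vertex_times]))
                keep = np.concatenate([[True],
                                       np.diff(times) > 1e-9 * max(dur, 1.0)])
                times = times[keep]
                times[-1] = dur
        return times


@dataclass
class _Timeline:
    """Shared timing/material bookkeeping for realization and ground truth."""

    t_pen_down: list[float]
    t_pen_up: list[float]
    select_color_at: list[Optional[float]]  # gap-start time if a select fires
    select_tool_at: list[Optional[float]]
    colors: list[str]
    tools: list[str]
    t_end: float


def _timeline(scripts: Sequence[StrokeScript], config: StudioConfig,
              final_gap: float) -> _Timeline:
    t = 0.0
    cur_color = config.palette[0]
    cur_tool = config.toolset[0]
    tl = _Timeline([], [], [], [], [], [], 0.0)
    for k, sc in enumerate(scripts):
        # the first stroke always gets explicit selections (as in a
        # calibration task); later ones only on an actual change
        tl.select_color_at.append(
            t if (sc.select and (k == 0 or sc.color != cur_color)) else None)
        tl.select_tool_at.append(
            t if (sc.select and (k == 0 or sc.tool != cur_tool)) else None)
        cur_color, cur_tool = sc.color, sc.tool
        t += sc.pre_gap
        tl.t_pen_down.append(t)
        t += sc.duration()
        tl.t_pen_up.append(t)
        tl.colors.append(sc.color)
        tl.tools.append(sc.tool)
    tl.t_end = t + final_gap
    return tl


def realize_scripts(scripts: Sequence[StrokeScript],
                    geometry: PageGeometry,
                    config: StudioConfig | None = None,
                    sample_rate: float = 100.0,
                    final_gap: float = 1.0,
                    meta: SessionMeta | None = None,
                    jitter_rng: np.random.Generator | None = None
                    ) -> SessionRecord:
    """Sample the scripts into a validated session record.

    Each stroke is sampled at ``sample_rate`` along its arc length at its
    constant speed (endpoints always included); selection events are
    emitted at the start of a stroke's pre-gap whenever its color or tool
    differs from the current one.  With ``jitter_rng``, interior sample
    times get uniform ±half-period jitter (robustness testing; off by
    default).
    """
    if config is None:
        config = StudioConfig()
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    for k, sc in enumerate(scripts):
        if sc.color not in config.palette:
            raise ValueError(f"script {k}: color {sc.color!r} not in palette")
        if sc.tool not in config.toolset:
            raise ValueError(f"script {k}: tool {sc.tool!r} not in toolset")
        pts = (sc.point_at(np.linspace(0, sc.length(), 64))
               if sc.primitive == "circle_arc" else sc.vertices())
        for x, y in np.atleast_2d(pts):
            if not geometry.contains(x, y):
                raise ValueError(f"script {k}: geometry leaves the page at "
                                 f"({x:.2f}, {y:.2f})")
    tl = _timeline(scripts, config, final_gap)
    events: list[SessionEvent] = [SessionEvent(t=0.0, kind="session_start")]
    for k, sc in enumerate(scripts):
        if tl.select_color_at[k] is not None:
            events.append(SessionEvent(t=tl.select_color_at[k],
                                       kind="select_color", color=sc.color))
        if tl.select_tool_at[k] is not None:
            events.append(SessionEvent(t=tl.select_tool_at[k],
                                       kind="select_tool", tool=sc.tool))
        rel = sc.sample_times(sample_rate)
        if jitter_rng is not None and len(rel) > 2:
            half = 0.5 * (rel[1] - rel[0])
            rel = rel.copy()
            rel[1:-1] += jitter_rng.uniform(-half, half, size=len(rel) - 2)
            rel.sort()
        pos = sc.point_at(sc.speed * rel)
        dur = sc.duration()
        pres = sc.pressure_profile(rel / dur if dur > 0 else rel)
        t0 = tl.t_pen_down[k]
        kinds = ["pen_down"] + ["pen_move"] * (len(rel) - 2) + ["pen_up"]
        if len(rel) == 1:
            kinds = ["pen_down"]
            events.append(SessionEvent(t=t0, kind="pen_down", x=pos[0, 0],
                                       y=pos[0, 1],
                                       pressure=float(np.clip(pres[0], 0, 1))))
            events.append(SessionEvent(t=t0, kind="pen_up", x=pos[0, 0],
                                       y=pos[0, 1],
                                       pressure=float(np.clip(pres[0], 0, 1))))
            continue
        for kind, tr, (x, y), p in zip(kinds, rel, pos, pres):
            events.append(SessionEvent(t=t0 + tr, kind=kind, x=float(x),
                                       y=float(y),
                                       pressure=float(np.clip(p, 0.0, 1.0))))
    events.append(SessionEvent(t=tl.t_end, kind="session_end"))
    return SessionRecord(geometry=geometry, config=config,
                         meta=meta or SessionMeta(), events=tuple(events))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Expected metrics of a scripted session, computed from the scripts.

    Integer/exact fields must be matched exactly by the pipeline;
    continuous fields to discretization tolerance.  ``*_sampled`` values
    are evaluated on the known sampling grid (closed-form positions at the
    grid times); ``*_exact`` values are the analytic arc-length limits.
    """

    session_duration: float
    drawing_time: float
    selecting_time: float
    drawing_pct: float
    idle_pct: float
    stroke_count: int
    total_stroke_length_exact: float
    total_stroke_length_sampled: float
    avg_stroke_length: float
    avg_velocity_exact: float
    avg_velocity_sampled: float
    avg_pressure: float
    avg_gradient: float
    strokes_per_second: float
    color_switches: int
    tool_switches: int
    switches_per_color: float
    colors_used_pct: float
    tools_used_pct: float
    erase_time_pct: float
    color_time: dict[str, float]
    tool_time: dict[str, float]
    quarter_time: dict[str, float]
    part_time: dict[str, float]
    cross_sections: dict[tuple[str, str], float]
    gradient_sector_time: dict[str, float]
    stroke_start_crossovers: int
    stroke_crossovers_h: int
    stroke_crossovers_v: int
    start_quarters: list[str]
    first_stroke_in_center: bool
    n_erase_epochs: int

    @property
    def quarter_pct(self) -> dict[str, float]:
        if self.drawing_time <= 0:
            return {}
        return {k: v / self.drawing_time * 100.0
                for k, v in self.quarter_time.items()}


def script_ground_truth(scripts: Sequence[StrokeScript],
                        geometry: PageGeometry,
                        config: StudioConfig | None = None,
                        sample_rate: float = 100.0,
                        final_gap: float = 1.0) -> GroundTruth:
    """Closed-form expected metrics for a script list.

    Uses only the script parameters, the sampling grid definition and the
    page partition rules — never the realized event stream.
    """
    if config is None:
        config = StudioConfig()
    tl = _timeline(scripts, config, final_gap)
    session_duration = tl.t_end
    durations = [sc.duration() for sc in scripts]
    drawing_time = float(sum(durations))
    # selection occupies from the select event (gap start) to the pen_down
    selecting_time = sum(
        tl.t_pen_down[k] - min(x for x in (tl.select_color_at[k],
                                           tl.select_tool_at[k])
                               if x is not None)
        for k in range(len(scripts))
        if tl.select_color_at[k] is not None or tl.select_tool_at[k] is not None)
    lengths_exact = [sc.length() for sc in scripts]
    total_exact = float(sum(lengths_exact))

    total_sampled = 0.0
    weighted_pressure = 0.0
    disp = np.zeros(2)
    quarter_time: dict[str, float] = {}
    part_time: dict[str, float] = {}
    sector_time: dict[str, float] = {}
    crossovers_h = crossovers_v = 0
    start_quarters: list[str] = []
    end_quarters: list[str] = []
    half_w, half_h = geometry.width / 2.0, geometry.height / 2.0
    from .statechart import gradient_angle, gradient_sector  # conventions

    for sc in scripts:
        rel = sc.sample_times(sample_rate)
        pos = sc.point_at(sc.speed * rel)
        dur = sc.duration()
        pres = np.clip(sc.pressure_profile(rel / dur if dur > 0 else rel),
                       0.0, 1.0)
        start_quarters.append(geometry.quarter(*pos[0]))
        end_quarters.append(geometry.quarter(*pos[-1]))
        if len(rel) < 2:
            continue
        dts = np.diff(rel)
        seg = np.diff(pos, axis=0)
        total_sampled += float(np.sum(np.linalg.norm(seg, axis=1)))
        weighted_pressure += float(np.sum(pres[:-1] * dts))
        disp += pos[-1] - pos[0]
        for i, dt in enumerate(dts):
            q = geometry.quarter(pos[i, 0], pos[i, 1])
            quarter_time[q] = quarter_time.get(q, 0.0) + float(dt)
            p = geometry.part(pos[i, 0], pos[i, 1])
            part_time[p] = part_time.get(p, 0.0) + float(dt)
            # left-hold gradient: interval i carries segment (i-1 -> i);
            # the first interval inherits the first segment's class
            j = max(0, i - 1)
            if np.hypot(*seg[j]) > 0:
                ang = gradient_angle(seg[j, 0], seg[j, 1])
            else:
                ang = 0.0
            sec = gradient_sector(ang)
            sector_time[sec] = sector_time.get(sec, 0.0) + float(dt)
        top = pos[:, 1] <= half_h
        left = pos[:, 0] <= half_w
        crossovers_h += int(np.sum(top[1:] != top[:-1]))
        crossovers_v += int(np.sum(left[1:] != left[:-1]))

    start_crossovers = sum(
        1 for k in range(1, len(scripts))
        if start_quarters[k] in
        {"Q1": {"Q2", "Q3"}, "Q2": {"Q1", "Q4"},
         "Q3": {"Q1", "Q4"}, "Q4": {"Q2", "Q3"}}[end_quarters[k - 1]])

    color_time: dict[str, float] = {}
    tool_time: dict[str, float] = {}
    cross: dict[tuple[str, str], float] = {}
    for sc, dur in zip(scripts, durations):
        tool_time[sc.tool] = tool_time.get(sc.tool, 0.0) + dur
        key = ERASE_PSEUDO_COLOR if sc.tool == "eraser" else sc.color
        color_time[key] = color_time.get(key, 0.0) + dur
        cross[(sc.color, sc.tool)] = cross.get((sc.color, sc.tool), 0.0) + dur

    colors = [sc.color for sc in scripts]
    tools = [sc.tool for sc in scripts]
    color_switches = sum(1 for a, b in zip(colors, colors[1:]) if a != b)
    tool_switches = sum(1 for a, b in zip(tools, tools[1:]) if a != b)
    colors_used = {sc.color for sc in scripts if sc.tool != "eraser"}
    n_erase_epochs = sum(
        1 for k, t in enumerate(tools)
        if t == "eraser" and (k == 0 or tools[k - 1] != "eraser"))

    if np.hypot(*disp) > 0:
        avg_gradient = math.degrees(math.atan2(-disp[1], disp[0]))
        if avg_gradient <= -180.0:
            avg_gradient += 360.0
    else:
        avg_gradient = 0.0
    pos_drawing = drawing_time > 0
    dpct = drawing_time / session_duration * 100.0 if session_duration > 0 else 0.0
    return GroundTruth(
        session_duration=session_duration,
        drawing_time=drawing_time,
        selecting_time=float(selecting_time),
        drawing_pct=dpct,
        idle_pct=100.0 - dpct,
        stroke_count=len(scripts),
        total_stroke_length_exact=total_exact,
        total_stroke_length_sampled=total_sampled,
        avg_stroke_length=total_exact / len(scripts) if scripts else 0.0,
        avg_velocity_exact=total_exact / drawing_time if pos_drawing else 0.0,
        avg_velocity_sampled=total_sampled / drawing_time if pos_drawing else 0.0,
        avg_pressure=weighted_pressure / drawing_time if pos_drawing else 0.0,
        avg_gradient=avg_gradient if pos_drawing else 0.0,
        strokes_per_second=len(scripts) / drawing_time if pos_drawing else 0.0,
        color_switches=color_switches,
        tool_switches=tool_switches,
        switches_per_color=(color_switches / len(colors_used)
                            if colors_used else 0.0),
        colors_used_pct=len(colors_used) / len(config.palette) * 100.0,
        tools_used_pct=len(set(tools)) / len(config.toolset) * 100.0,
        erase_time_pct=(tool_time.get("eraser", 0.0) / drawing_time * 100.0
                        if pos_drawing else 0.0),
        color_time=color_time,
        tool_time=tool_time,
        quarter_time=quarter_time,
        part_time=part_time,
        cross_sections=cross,
        gradient_sector_time=sector_time,
        stroke_start_crossovers=start_crossovers,
        stroke_crossovers_h=crossovers_h,
        stroke_crossovers_v=crossovers_v,
        start_quarters=start_quarters,
        first_stroke_in_center=bool(scripts) and
        geometry.part(*np.atleast_2d(scripts[0].point_at(0.0))[0]) == "center",
        n_erase_epochs=n_erase_epochs,
    )


#: Fields of GroundTruth that the pipeline must reproduce exactly.
EXACT_FIELDS = (
    "stroke_count", "color_switches", "tool_switches",
    "stroke_start_crossovers", "stroke_crossovers_h", "stroke_crossovers_v",
    "first_stroke_in_center",
)

#: (ground-truth field, MetricsTable field) pairs compared at relative tol.
CONTINUOUS_FIELDS = (
    ("session_duration", "session_duration"),
    ("drawing_time", "drawing_time"),
    ("drawing_pct", "drawing_pct"),
    ("idle_pct", "idle_pct"),
    ("selecting_time", "selecting_time"),
    ("total_stroke_length_exact", "total_stroke_length"),
    ("avg_stroke_length", "avg_stroke_length"),
    ("avg_velocity_exact", "avg_velocity"),
    ("avg_pressure", "avg_pressure"),
    ("avg_gradient", "avg_gradient"),
    ("strokes_per_second", "strokes_per_second"),
    ("switches_per_color", "switches_per_color"),
    ("colors_used_pct", "colors_used_pct"),
    ("tools_used_pct", "tools_used_pct"),
    ("erase_time_pct", "erase_time_pct"),
)


def ground_truth_errors(gt: GroundTruth, metrics) -> tuple[dict, dict]:
    """Compare a computed metrics table against its ground truth.

    Returns ``(exact_mismatches, relative_errors)``: exact fields that
    differ, and per-field relative errors (absolute error where the truth
    is ~0) for continuous fields including per-color/tool/quarter times.
    """
    mism = {}
    for name in EXACT_FIELDS:
        a, b = getattr(metrics, name), getattr(gt, name)
        if int(a) != int(b):
            mism[name] = (a, b)
    rel = {}

    def _err(key, got, want):
        scale = max(abs(want), 1e-9)
        rel[key] = abs(got - want) / scale if abs(want) > 1e-9 else abs(got - want)

    for gt_name, m_name in CONTINUOUS_FIELDS:
        _err(m_name, float(getattr(metrics, m_name)), float(getattr(gt, gt_name)))
    for key, want in gt.color_time.items():
        _err(f"color_time:{key}", metrics.color_time.get(key, 0.0), want)
    for key, want in gt.tool_time.items():
        _err(f"tool_time:{key}", metrics.tool_time.get(key, 0.0), want)
    for key, want in gt.quarter_time.items():
        _err(f"quarter_time:{key}", metrics.quarter_time.get(key, 0.0), want)
    for key, want in gt.cross_sections.items():
        _err(f"cross:{key}", metrics.cross_sections.get(key, 0.0), want)
    want_center = gt.part_time.get("center", 0.0)
    got_center = (metrics.center_pct / 100.0 * metrics.drawing_time
                  if metrics.drawing_time > 0 else 0.0)
    _err("center_time", got_center, want_center)
    return mism, rel


# ---------------------------------------------------------------------------
# random cohorts


@dataclass(frozen=True)
class GroupParams:
    """Per-group session distributions for cohort generation."""

    stroke_count_mean: float = 12.0
    speed_median: float = 8.0  # cm/s, log-normal median
    speed_sigma: float = 0.4  # log-scale sigma
    pressure_mean: float = 0.6
    pressure_sd: float = 0.08
    color_weights: Optional[tuple[float, ...]] = None  # Dirichlet over palette
    erase_p: float = 0.15
    idle_alpha: float = 2.0  # Beta prior of the session idle fraction
    idle_beta: float = 2.0
    speed_scale: float = 1.0  # multiplier applied to every stroke speed


@dataclass(frozen=True)
class CohortSpec:
    """A two-(or more-)group cohort layout with planted distributions."""

    seed: int
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: {"female": GroupParams(), "male": GroupParams()})
    group_label: str = "gender"
    subjects_per_group: int = 6
    tasks: tuple[str, ...] = ("positive", "negative", "htp")
    sample_rate: float = 50.0
    geometry: PageGeometry = field(
        default_factory=lambda: PageGeometry(width=20.0, height=20.0))
    config: StudioConfig = field(default_factory=StudioConfig)


def _random_session_scripts(rng: np.random.Generator, g: GroupParams,
                            geometry: PageGeometry,
                            config: StudioConfig) -> list[StrokeScript]:
    n = max(1, int(rng.poisson(g.stroke_count_mean)))
    weights = (np.asarray(g.color_weights, dtype=float)
               if g.color_weights is not None
               else np.ones(len(config.palette)))
    weights = weights / weights.sum()
    idle_frac = float(rng.beta(g.idle_alpha, g.idle_beta))
    idle_frac = min(idle_frac, 0.95)
    tools_no_eraser = [t for t in config.toolset if t != "eraser"] or \
        list(config.toolset)
    margin = 1.0
    w, h = geometry.width, geometry.height
    scripts = []
    color = str(rng.choice(np.array(config.palette), p=weights))
    tool = str(rng.choice(tools_no_eraser))
    for _ in range(n):
        if rng.random() < 0.4:
            color = str(rng.choice(np.array(config.palette), p=weights))
        if rng.random() < 0.25:
            tool = ("eraser" if rng.random() < g.erase_p
                    else str(rng.choice(tools_no_eraser)))
        speed = float(np.exp(np.log(g.speed_median)
                             + g.speed_sigma * rng.standard_normal()))
        speed *= g.speed_scale
        pressure = float(np.clip(rng.normal(g.pressure_mean, g.pressure_sd),
                                 0.05, 0.95))
        n_pts = int(rng.integers(2, 5))
        pts = np.column_stack([rng.uniform(margin, w - margin, n_pts),
                               rng.uniform(margin, h - margin, n_pts)])
        # expected stroke duration at this group's typical speed
        length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        exp_dur = length / speed
        gap = float(rng.exponential(
            max(1e-3, idle_frac / (1.0 - idle_frac) * max(exp_dur, 0.2))))
        scripts.append(StrokeScript(
            primitive="polyline", color=color, tool=tool, speed=speed,
            pressure=pressure, pre_gap=0.2 + gap,
            points=tuple(map(tuple, pts))))
    return scripts


def generate_cohort(spec: CohortSpec) -> list[SessionRecord]:
    """Draw a full cohort of synthetic sessions, deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for group in sorted(spec.groups):
        g = spec.groups[group]
        for i in range(spec.subjects_per_group):
            subject = f"{group[:1]}{i:02d}"
            for task in spec.tasks:
                scripts = _random_session_scripts(rng, g, spec.geometry,
                                                  spec.config)
                meta = SessionMeta(subject=subject, task=task,
                                   groups={spec.group_label: group})
                records.append(realize_scripts(
                    scripts, spec.geometry, spec.config,
                    sample_rate=spec.sample_rate, meta=meta))
    return records


def random_session(seed: int, params: GroupParams | None = None,
                   geometry: PageGeometry | None = None,
                   config: StudioConfig | None = None,
                   sample_rate: float = 50.0
                   ) -> tuple[SessionRecord, GroundTruth]:
    """One random session plus its ground truth (property-test helper)."""
    rng = np.random.default_rng(seed)
    params = params or GroupParams()
    geometry = geometry or PageGeometry(width=20.0, height=20.0)
    config = config or StudioConfig()
    scripts = _random_session_scripts(rng, params, geometry, config)
    record = realize_scripts(scripts, geometry, config, sample_rate=sample_rate)
    gt = script_ground_truth(scripts, geometry, config, sample_rate=sample_rate)
    return record, gt


# ---------------------------------------------------------------------------
# bundled fixtures


def _three_object_scripts() -> list[StrokeScript]:
    """Rectangle, diamond, circle — plus an object drawn in Q4 and then
    fully erased by six eraser strokes (one erase epoch)."""
    scripts = [
        # red oils rectangle in Q1, clockwise
        StrokeScript("polyline", color="red", tool="oils", speed=6.0,
                     pressure=0.7, pre_gap=1.0,
                     points=((2.0, 2.0), (8.0, 2.0), (8.0, 7.0), (2.0, 7.0),
                             (2.0, 2.0))),
        # two green back-and-forth lines over the rectangle
        StrokeScript("polyline", color="green", tool="oils", speed=3.0,
                     pressure=0.6, pre_gap=0.8,
                     points=((2.2, 2.0), (7.8, 2.0), (2.2, 2.0), (7.8, 2.0))),
        # blue water-color diamond in Q2
        StrokeScript("polyline", color="blue", tool="water color", speed=5.0,
                     pressure=0.55, pre_gap=1.2,
                     points=((5.0, 12.0), (8.0, 15.0), (5.0, 18.0),
                             (2.0, 15.0), (5.0, 12.0))),
        # orange pencil diagonal through the diamond
        StrokeScript("line", color="orange", tool="pencil", speed=2.0,
                     pressure=0.5, pre_gap=0.7,
                     points=((2.5, 17.5), (7.5, 12.5))),
        # yellow ink counter-clockwise circle in Q3
        StrokeScript("circle_arc", color="yellow", tool="ink pen", speed=7.0,
                     pressure=0.6, pre_gap=1.0, center=(15.0, 5.0),
                     radius=2.4, theta0=0.0, theta1=360.0),
        # the doomed Q4 object: white zigzag, black stroke, two diagonals
        StrokeScript("zigzag", color="white", tool="pastel", speed=6.0,
                     pressure=(0.3, 0.6), pre_gap=1.0,
                     points=((12.6, 15.0), (17.4, 15.0)), amplitude=1.6,
                     cycles=3),
        StrokeScript("line", color="black", tool="pastel", speed=5.0,
                     pressure=(0.35, 0.65), pre_gap=0.5,
                     points=((15.0, 13.3), (15.0, 16.7))),
        StrokeScript("line", color="skin", tool="pastel", speed=5.0,
                     pressure=(0.4, 0.7), pre_gap=0.5,
                     points=((12.8, 13.4), (17.2, 16.6))),
        StrokeScript("line", color="pink", tool="pastel", speed=5.0,
                     pressure=(0.45, 0.75), pre_gap=0.5,
                     points=((13.0, 16.5), (17.3, 13.4))),
    ]
    # six horizontal eraser strokes sweeping the whole Q4 object
    for k in range(6):
        y = 13.0 + 0.8 * k
        scripts.append(StrokeScript(
            "line", color="pink", tool="eraser", speed=10.0, pressure=0.8,
            pre_gap=0.3 if k else 1.5, points=((12.0, y), (18.0, y))))
    return scripts


def _vertical_mass_scripts() -> list[StrokeScript]:
    """Long black pastel zigzags with near-vertical legs (fast, heavy)."""
    scripts = []
    for k in range(4):
        y0 = 10.0
        scripts.append(StrokeScript(
            "zigzag", color="black", tool="pastel", speed=25.0,
            pressure=(0.5, 0.9), pre_gap=0.4 if k else 1.0,
            points=((2.5 + 0.3 * k, y0), (17.5 - 0.3 * k, y0)),
            amplitude=8.5, cycles=7))
    return scripts


FIXTURE_SCRIPTS = {
    "three-object": _three_object_scripts,
    "vertical-mass": _vertical_mass_scripts,
    "empty": lambda: [],
    "single-dot": lambda: [StrokeScript("line", color="black", tool="pencil",
                                        speed=5.0, pressure=0.5, pre_gap=1.0,
                                        points=((10.0, 10.0), (10.0, 10.0)))],
}


def bundled_fixtures(sample_rate: float = 100.0
                     ) -> dict[str, tuple[SessionRecord, GroundTruth]]:
    """The named fixture sessions with their ground truths."""
    geometry = PageGeometry(width=20.0, height=20.0)
    config = StudioConfig()
    out = {}
    for name, factory in FIXTURE_SCRIPTS.items():
        scripts = factory()
        record = realize_scripts(scripts, geometry, config,
                                 sample_rate=sample_rate,
                                 meta=SessionMeta(subject="fixture", task=name))
        gt = script_ground_truth(scripts, geometry, config,
                                 sample_rate=sample_rate)
        out[name] = (record, gt)
    return out


def fixture_suite(n_random: int = 16, seed: int = 20240901,
                  sample_rate: float = 100.0
                  ) -> list[tuple[str, SessionRecord, GroundTruth]]:
    """Bundled fixtures plus seeded random scripted sessions (≥20 total)."""
    out = [(name, rec, gt) for name, (rec, gt)
           in bundled_fixtures(sample_rate).items()]
    rng = np.random.default_rng(seed)
    geometry = PageGeometry(width=20.0, height=20.0)
    config = StudioConfig()
    for k in range(n_random):
        scripts = _random_session_scripts(rng, GroupParams(), geometry, config)
        rec = realize_scripts(scripts, geometry, config,
                              sample_rate=sample_rate,
                              meta=SessionMeta(subject=f"rand{k}", task="free"))
        gt = script_ground_truth(scripts, geometry, config,
                                 sample_rate=sample_rate)
        out.append((f"random-{k}", rec, gt))
    return out
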