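"""Documentation outputs: canvas playback, visual report, textual report.

The visual report is a one-page temporal plot of the session: categorical
bands for color, tool, page quarter and center/boundary occupancy, line
tracks for pressure and drawing direction, shading over erase epochs, a
stroke on/off band, and inline canvas snapshots.  The textual report is a
fixed-layout plain-text rendering of the full metrics table, parseable
back into the values it prints.  Playback renders the canvas at any
session time: stroke segments are swept discs of the tool width, and the
eraser restores the page background along its sweep.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib.figure import Figure
from PIL import Image

from .metrics import MetricsTable, compute_metrics
from .session import SessionRecord, Stroke, extract_strokes
from .statechart import TimedTrace, run as run_statechart

#: Page background: off-white yellowish so white ink stays visible.
BACKGROUND_RGB = (247, 243, 225)

COLOR_RGB = {
    "yellow": (240, 214, 40),
    "red": (201, 44, 38),
    "blue": (43, 78, 198),
    "orange": (236, 136, 24),
    "violet": (128, 62, 176),
    "green": (58, 156, 74),
    "black": (24, 24, 24),
    "white": (255, 255, 255),
    "pink": (238, 146, 188),
    "skin": (227, 184, 146),
}
_FALLBACK_RGB = (120, 120, 120)


def color_rgb(name: str) -> tuple[int, int, int]:
    return COLOR_RGB.get(name, _FALLBACK_RGB)


# ---------------------------------------------------------------------------
# canvas playback


@dataclass
class CanvasImage:
    """RGB raster of the page at a session time."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixels_per_cm: float
    t: float

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(Path(path), format="PNG")

    def inked_mask(self) -> np.ndarray:
        """Pixels differing from the page background."""
        bg = np.array(BACKGROUND_RGB, dtype=np.uint8)
        return np.any(self.pixels != bg, axis=2)


def _stamp_segment(img: np.ndarray, ppcm: float, p0, p1, radius_cm: float,
                   rgb: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    r = radius_cm * ppcm
    x0, y0 = p0[0] * ppcm, p0[1] * ppcm
    x1, y1 = p1[0] * ppcm, p1[1] * ppcm
    j0 = max(0, int(min(x0, x1) - r - 1))
    j1 = min(w, int(math.ceil(max(x0, x1) + r + 1)))
    i0 = max(0, int(min(y0, y1) - r - 1))
    i1 = min(h, int(math.ceil(max(y0, y1) + r + 1)))
    if j0 >= j1 or i0 >= i1:
        return
    gx = np.arange(j0, j1) + 0.5
    gy = (np.arange(i0, i1) + 0.5)[:, None]
    vx, vy = x1 - x0, y1 - y0
    denom = vx * vx + vy * vy
    if denom == 0:
        d2 = (gx - x0) ** 2 + (gy - y0) ** 2
    else:
        t = ((gx - x0) * vx + (gy - y0) * vy) / denom
        t = np.clip(t, 0.0, 1.0)
        d2 = (gx - (x0 + t * vx)) ** 2 + (gy - (y0 + t * vy)) ** 2
    sel = d2 <= r * r
    region = img[i0:i1, j0:j1]
    region[sel] = rgb


def render_canvas(record: SessionRecord, t: float,
                  pixels_per_cm: float = 10.0,
                  strokes: Sequence[Stroke] | None = None) -> CanvasImage:
    """Deterministic raster of the artwork as of session time ``t``.

    All stroke segments whose samples fall at or before ``t`` are drawn in
    stream order; eraser strokes paint the page background (destination-out
    sweep).  Partially elapsed strokes are drawn up to their last sample
    ≤ t.
    """
    if not (record.t_start <= t <= record.t_end):
        raise ValueError(f"t={t} outside session span "
                         f"[{record.t_start}, {record.t_end}]")
    if strokes is None:
        strokes = extract_strokes(record)
    w = max(1, int(round(record.geometry.width * pixels_per_cm)))
    h = max(1, int(round(record.geometry.height * pixels_per_cm)))
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    for s in strokes:
        if s.t0 > t:
            break
        rgb = BACKGROUND_RGB if s.tool == "eraser" else color_rgb(s.color)
        radius = record.config.tool_width(s.tool) / 2.0
        pts = s.samples[s.samples[:, 0] <= t, 1:3]
        if len(pts) == 0:
            continue
        if len(pts) == 1:
            _stamp_segment(img, pixels_per_cm, pts[0], pts[0], radius, rgb)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _stamp_segment(img, pixels_per_cm, p0, p1, radius, rgb)
    return CanvasImage(pixels=img, pixels_per_cm=pixels_per_cm, t=t)


# ---------------------------------------------------------------------------
# visual report


@dataclass
class VisualReportSpec:
    """Layout knobs for the visual report."""

    tracks: tuple[str, ...] = ("strokes", "colors", "tools", "quarters",
                               "parts", "pressure", "gradient")
    snapshot_times: Optional[tuple[float, ...]] = None  # default: stroke quartiles
    n_snapshots: int = 4
    figsize: tuple[float, float] = (11.0, 8.0)
    dpi: int = 100
    pixels_per_cm: float = 6.0


_TAB10 = [(31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
          (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
          (188, 189, 34), (23, 190, 207)]


def _to01(rgb: tuple[int, int, int]) -> tuple[float, float, float]:
    return tuple(c / 255.0 for c in rgb)


def _default_snapshot_times(strokes: Sequence[Stroke], t_end: float,
                            n: int) -> list[float]:
    """End times of the strokes at count quartiles (plus session end)."""
    if not strokes:
        return [t_end]
    ends = [s.t1 for s in strokes]
    idx = [max(0, int(round(q * len(ends))) - 1)
           for q in np.linspace(1.0 / n, 1.0, n)]
    return sorted(set(ends[i] for i in idx))


def visual_report(record: SessionRecord,
                  spec: VisualReportSpec | None = None,
                  path: str | Path | None = None,
                  trace: TimedTrace | None = None) -> Figure:
    """Render the one-page temporal report; optionally save it as PNG.

    All interval bands are read off the statechart trace so that the plot
    shows exactly the states the tracker occupied.  Saved output is
    byte-stable for fixed input, spec and dpi.
    """
    spec = spec or VisualReportSpec()
    if trace is None:
        trace = run_statechart(record)
    strokes = extract_strokes(record)
    t0, t1 = trace.t_start, max(trace.t_end, trace.t_start + 1e-9)

    fig = Figure(figsize=spec.figsize, dpi=spec.dpi)
    n_tracks = len(spec.tracks)
    gs = fig.add_gridspec(n_tracks + 2, 1,
                          height_ratios=[2.2, 0.3] + [1.0] * n_tracks,
                          hspace=0.45)

    # snapshots row
    snap_times = (list(spec.snapshot_times) if spec.snapshot_times is not None
                  else _default_snapshot_times(strokes, t1, spec.n_snapshots))
    snap_ax = fig.add_subplot(gs[0])
    snap_ax.set_axis_off()
    if snap_times:
        width = 1.0 / len(snap_times)
        for k, ts in enumerate(snap_times):
            inset = snap_ax.inset_axes([k * width + 0.01, 0.0,
                                        width - 0.02, 0.95])
            canvas = render_canvas(record, min(ts, record.t_end),
                                   pixels_per_cm=spec.pixels_per_cm,
                                   strokes=strokes)
            inset.imshow(canvas.pixels, interpolation="nearest")
            inset.set_title(f"t={ts:.0f}s", fontsize=7)
            inset.set_xticks([])
            inset.set_yticks([])

    erase_epochs = [(iv.t_start, iv.t_end)
                    for iv in trace.intervals_for("tool:eraser")]

    axes = []
    for k, track in enumerate(spec.tracks):
        ax = fig.add_subplot(gs[k + 2])
        axes.append(ax)
        ax.set_xlim(t0, t1)
        ax.set_ylabel(track, rotation=0, ha="right", va="center", fontsize=8)
        ax.tick_params(labelsize=7)
        if track == "strokes":
            for iv in trace.intervals_for("Painting"):
                ax.axvspan(iv.t_start, iv.t_end, color="0.35")
            ax.set_yticks([])
        elif track == "colors":
            for iv in trace.leaf_intervals("color"):
                name = iv.state.split(":", 1)[1]
                ax.axvspan(iv.t_start, iv.t_end, color=_to01(color_rgb(name)))
            ax.set_yticks([])
        elif track == "tools":
            tools = list(record.config.toolset)
            for iv in trace.leaf_intervals("tool"):
                name = iv.state.split(":", 1)[1]
                c = _to01(_TAB10[tools.index(name) % len(_TAB10)]) \
                    if name in tools else _to01(_FALLBACK_RGB)
                ax.axvspan(iv.t_start, iv.t_end, color=c)
            ax.set_yticks([])
        elif track == "quarters":
            order = {"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}
            for iv in trace.leaf_intervals("quarter"):
                q = iv.state.split(":", 1)[1]
                ax.broken_barh([(iv.t_start, iv.duration)],
                               (order[q], 0.8),
                               color=_to01(_TAB10[order[q]]))
            ax.set_yticks([0.4, 1.4, 2.4, 3.4])
            ax.set_yticklabels(["Q1", "Q2", "Q3", "Q4"], fontsize=6)
            ax.set_ylim(-0.2, 4.0)
        elif track == "parts":
            for iv in trace.leaf_intervals("part"):
                p = iv.state.split(":", 1)[1]
                y = 0 if p == "center" else 1
                ax.broken_barh([(iv.t_start, iv.duration)], (y, 0.8),
                               color=_to01(_TAB10[y + 4]))
            ax.set_yticks([0.4, 1.4])
            ax.set_yticklabels(["center", "boundary"], fontsize=6)
            ax.set_ylim(-0.2, 2.0)
        elif track == "pressure":
            for s in strokes:
                ax.plot(s.samples[:, 0], s.samples[:, 3],
                        color="tab:blue", lw=0.8)
            ax.set_ylim(0, 1.05)
        elif track == "gradient":
            for s in strokes:
                if len(s) < 2:
                    continue
                d = np.diff(s.xy, axis=0)
                ang = np.degrees(np.arctan2(-d[:, 1], d[:, 0]))
                ts = s.samples[1:, 0]
                # break the line at ±180 wraps instead of drawing jumps
                wraps = np.abs(np.diff(ang)) > 180.0
                ang_plot = ang.copy()
                segments = np.split(np.arange(len(ang)),
                                    np.nonzero(wraps)[0] + 1)
                for seg in segments:
                    if len(seg):
                        ax.plot(ts[seg], ang_plot[seg], color="tab:red", lw=0.8)
            ax.set_ylim(-185, 185)
            ax.set_yticks([-180, -90, 0, 90, 180])
        for e0, e1 in erase_epochs:
            ax.axvspan(e0, e1, color="0.55", alpha=0.35, lw=0)
    if axes:
        axes[-1].set_xlabel("session time (s)", fontsize=8)
    fig.suptitle(f"session {record.meta.subject} / {record.meta.task}",
                 fontsize=10)
    if path is not None:
        save_figure(fig, path)
    return fig


def save_figure(fig: Figure, path: str | Path) -> None:
    """Save a figure as PNG with volatile metadata stripped (byte-stable)."""
    fig.savefig(Path(path), format="png", metadata={"Software": None})


# ---------------------------------------------------------------------------
# textual report


_SECTIONS: list[tuple[str, list[tuple[str, str, str]]]] = [
    ("session", [
        ("session duration", "session_duration", "{:.1f} s"),
        ("net drawing time", "drawing_time", "{:.1f} s"),
        ("drawing time", "drawing_pct", "{:.1f}%"),
        ("idle time", "idle_pct", "{:.1f}%"),
        ("selecting time", "selecting_time", "{:.1f} s"),
    ]),
    ("strokes", [
        ("stroke count", "stroke_count", "{:.0f}"),
        ("total stroke length", "total_stroke_length", "{:.1f} cm"),
        ("average stroke length", "avg_stroke_length", "{:.2f} cm"),
        ("average velocity", "avg_velocity", "{:.2f} cm/s"),
        ("average pressure", "avg_pressure", "{:.3f}"),
        ("average gradient", "avg_gradient", "{:.1f} deg"),
        ("strokes per second", "strokes_per_second", "{:.2f} 1/s"),
    ]),
    ("materials", [
        ("colors used", "colors_used_pct", "{:.1f}% of palette"),
        ("tools used", "tools_used_pct", "{:.1f}% of toolset"),
        ("color switches", "color_switches", "{:.0f}"),
        ("tool switches", "tool_switches", "{:.0f}"),
        ("switches per color", "switches_per_color", "{:.2f}"),
        ("erase time", "erase_time_pct", "{:.1f}%"),
    ]),
    ("page use", [
        ("area used", "area_used_pct", "{:.1f}% of page"),
        ("center", "center_pct", "{:.1f}%"),
        ("boundary", "boundary_pct", "{:.1f}%"),
        ("stroke start crossovers", "stroke_start_crossovers", "{:.0f}"),
        ("horizontal crossovers", "stroke_crossovers_h", "{:.0f}"),
        ("vertical crossovers", "stroke_crossovers_v", "{:.0f}"),
    ]),
]

_LABEL_TO_FIELD = {label: fieldname
                   for _, rows in _SECTIONS for label, fieldname, _ in rows}


def textual_report(metrics: MetricsTable) -> str:
    """Fixed-layout plain-text report of a session's metrics table.

    Percentages print with one decimal.  :func:`parse_textual_report`
    recovers every printed value.
    """
    lines: list[str] = ["=== art session report ==="]
    if metrics.degenerate:
        lines.append("(degenerate session: no positive drawing time)")
    for section, rows in _SECTIONS:
        lines.append("")
        lines.append(f"--- {section} ---")
        for label, fieldname, fmt in rows:
            lines.append(f"{label}: " + fmt.format(float(getattr(metrics, fieldname))))
        if section == "materials":
            for color in (*metrics.palette, "erase"):
                if color in metrics.color_pct:
                    lines.append(f"color {color}: "
                                 f"{metrics.color_pct[color]:.1f}%")
            for tool in metrics.toolset:
                if tool in metrics.tool_pct:
                    lines.append(f"tool {tool}: {metrics.tool_pct[tool]:.1f}%")
        if section == "page use":
            for q in ("Q1", "Q2", "Q3", "Q4"):
                lines.append(f"quarter {q}: {metrics.quarter_pct.get(q, 0.0):.1f}%")
            lines.append("first stroke in center: "
                         + ("yes" if metrics.first_stroke_in_center else "no"))
    lines.append("")
    lines.append("--- cross sections (color x tool) ---")
    for (color, tool), secs in sorted(metrics.cross_sections.items()):
        lines.append(f"{color} / {tool}: {secs:.1f} s")
    return "\n".join(lines) + "\n"


_VALUE_RE = re.compile(r"^(?P<label>[^:]+): (?P<value>-?\d+(?:\.\d+)?)")


def parse_textual_report(text: str) -> dict[str, float | dict]:
    """Parse a textual report back into the values it prints."""
    out: dict[str, float | dict] = {
        "color_pct": {}, "tool_pct": {}, "quarter_pct": {},
        "cross_sections": {},
    }
    for line in text.splitlines():
        if line.startswith("first stroke in center:"):
            out["first_stroke_in_center"] = float(line.endswith("yes"))
            continue
        m = _VALUE_RE.match(line)
        if not m:
            continue
        label, value = m.group("label").strip(), float(m.group("value"))
        if label in _LABEL_TO_FIELD:
            out[_LABEL_TO_FIELD[label]] = value
        elif label.startswith("color "):
            out["color_pct"][label[6:]] = value
        elif label.startswith("tool "):
            out["tool_pct"][label[5:]] = value
        elif label.startswith("quarter "):
            out["quarter_pct"][label[8:]] = value
        elif " / " in label:
            color, tool = label.split(" / ", 1)
            out["cross_sections"][(color, tool)] = value
    return out


def session_report(record: SessionRecord, out_dir: str | Path,
                   spec: VisualReportSpec | None = None) -> MetricsTable:
    """Write the full documentation bundle for one session.

    Produces ``report.txt`` (textual), ``report.png`` (visual),
    ``metrics.csv`` and ``trace.csv`` under ``out_dir``; returns the
    metrics table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace = run_statechart(record)
    metrics = compute_metrics(record, trace=trace)
    (out / "report.txt").write_text(textual_report(metrics), encoding="utf-8")
    visual_report(record, spec=spec, path=out / "report.png", trace=trace)
    flat = metrics.flatten()
    pd.Series(flat, name="value").rename_axis("metric").to_csv(out / "metrics.csv")
    trace.to_dataframe().to_csv(out / "trace.csv", index=False)
    return metrics
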