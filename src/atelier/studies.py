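"""Monte-Carlo studies of the cohort statistics.

Two canned simulations back the statistical machinery:

* :func:`null_calibration` — the type-I error of the Welch t-test, the
  rank-sum test and the "significant under both" rule when both groups
  are drawn from the same distribution (the study's n = 6 per group);
* :func:`velocity_power_study` — the power to recover a planted shift in
  drawing velocity through the full pipeline: cohorts of synthetic
  sessions are generated, per-session kinematic metrics computed, and
  the group scan run on each replicate.  The planted effect is a speed
  multiplier calibrated so the session-level avg_velocity mean moves by
  a chosen number of null standard deviations (scaling every stroke
  speed by k scales a session's avg_velocity by exactly k).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import scan_metrics, two_sample_tests
from .metrics import session_kinematics, switch_counts
from .session import SessionRecord, extract_strokes
from .synth import CohortSpec, GroupParams, generate_cohort

#: Kinematic/switch metrics used by the pipeline power study.
KINEMATIC_METRICS = (
    "avg_velocity", "avg_pressure", "avg_stroke_length", "strokes_per_second",
    "total_stroke_length", "stroke_count", "drawing_pct",
    "color_switches", "tool_switches",
)


def null_calibration(n_reps: int = 2000, n_per_group: int = 6,
                     alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Rejection rates under the null (both groups standard normal).

    Returns rates for the t-test, the rank-sum test and the both-tests
    rule at the given alpha.
    """
    rng = np.random.default_rng(seed)
    rej_t = rej_rank = rej_both = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        ts = two_sample_tests(a, b)
        st = ts.t_p < alpha
        sr = ts.rank_p < alpha
        rej_t += st
        rej_rank += sr
        rej_both += st and sr
    return {"t": rej_t / n_reps, "rank": rej_rank / n_reps,
            "both": rej_both / n_reps, "alpha": alpha, "n_reps": n_reps}


def kinematic_frame(records: list[SessionRecord],
                    group_label: str) -> pd.DataFrame:
    """Cheap per-session metric frame (no statechart, no raster)."""
    rows = []
    for rec in records:
        strokes = extract_strokes(rec)
        kin = session_kinematics(strokes)
        sw = switch_counts(strokes, rec.config)
        duration = rec.duration
        rows.append({
            "subject": rec.meta.subject, "task": rec.meta.task,
            group_label: rec.meta.groups.get(group_label, ""),
            "avg_velocity": kin.avg_velocity,
            "avg_pressure": kin.avg_pressure,
            "avg_stroke_length": kin.avg_stroke_length,
            "strokes_per_second": kin.strokes_per_second,
            "total_stroke_length": kin.total_stroke_length,
            "stroke_count": len(strokes),
            "drawing_pct": (kin.drawing_time / duration * 100.0
                            if duration > 0 else 0.0),
            "color_switches": sw.color_switches,
            "tool_switches": sw.tool_switches,
        })
    return pd.DataFrame(rows)


def _power_spec(seed: int, speed_scale_a: float = 1.0) -> CohortSpec:
    # scaled-down single-task cohorts keep the replicated study tractable
    base = GroupParams(stroke_count_mean=6.0, speed_median=8.0,
                       speed_sigma=0.4, erase_p=0.1)
    return CohortSpec(
        seed=seed,
        groups={"A": replace(base, speed_scale=speed_scale_a), "B": base},
        group_label="group",
        subjects_per_group=6,
        tasks=("task",),
        sample_rate=30.0,
    )


def planted_speed_scale(shift_sd: float = 2.0, n_calibration: int = 200,
                        seed: int = 7_654_321) -> float:
    """Speed multiplier that shifts mean avg_velocity by ``shift_sd``
    null standard deviations, estimated from a seeded null run."""
    records = generate_cohort(_power_spec(seed))
    frame = kinematic_frame(records, "group")
    v = frame["avg_velocity"].to_numpy(float)
    return 1.0 + shift_sd * v.std(ddof=1) / v.mean()


def velocity_power_study(n_reps: int = 1000, alpha: float = 0.05,
                         shift_sd: float = 2.0, seed: int = 1,
                         speed_scale: float | None = None) -> dict:
    """Power and false-flag rates of the full generate→measure→scan loop.

    Each replicate generates a fresh 6+6-subject single-task cohort with
    group A's stroke speeds scaled to plant a ``shift_sd``-SD shift in
    avg_velocity, computes the kinematic metric frame, and scans all
    metrics for group differences.  Returns the flag rate (both-tests
    rule) for avg_velocity and for each truly-null metric.
    """
    if speed_scale is None:
        speed_scale = planted_speed_scale(shift_sd)
    rng = np.random.default_rng(seed)
    flags = {m: 0 for m in KINEMATIC_METRICS}
    flags_t = {m: 0 for m in KINEMATIC_METRICS}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        records = generate_cohort(_power_spec(rep_seed, speed_scale))
        frame = kinematic_frame(records, "group")
        results = scan_metrics(frame, "group", alpha=alpha,
                               metrics=KINEMATIC_METRICS)
        for r in results:
            if r.significant_both:
                flags[r.metric] += 1
            if r.significant_t:
                flags_t[r.metric] += 1
    # strokes_per_second is n/drawing-time, so a speed plant moves it too;
    # the truly-null set is every metric the plant leaves distributionally
    # unchanged
    null_metrics = [m for m in KINEMATIC_METRICS
                    if m not in ("avg_velocity", "strokes_per_second")]
    return {
        "power_velocity": flags["avg_velocity"] / n_reps,
        "power_velocity_t": flags_t["avg_velocity"] / n_reps,
        "null_flag_rates": {m: flags[m] / n_reps for m in null_metrics},
        "max_null_flag_rate": max(flags[m] / n_reps for m in null_metrics),
        "speed_scale": speed_scale,
        "n_reps": n_reps,
        "alpha": alpha,
    }
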