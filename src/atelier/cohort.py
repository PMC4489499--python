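"""Group-difference analysis over per-session metric tables.

Sessions are aggregated into a cohort frame (one row per subject × task)
and each metric is compared between two groups with both a Welch t-test
on means and a Wilcoxon rank-sum (Mann-Whitney U) test on the same
values; the headline convention flags a metric only when it is
significant under *both* tests.  Raw p-values are reported with no
multiplicity correction by default; a Benjamini–Hochberg column is
available as a clearly-marked extension.

The rank-sum test is exact when the combined sample is ≤ 20 with no
ties, and otherwise uses the normal approximation with tie correction
(no continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import compute_metrics
from .session import SessionRecord

META_COLUMNS = ("subject", "task")


def aggregate(records: Sequence[SessionRecord],
              use_trace: bool = True) -> pd.DataFrame:
    """Compute metrics per session and join the session metadata.

    Returns one row per (subject, task) with the flattened metric columns
    plus the subject's group labels; duplicate (subject, task) pairs and
    mixed studio configurations are rejected.
    """
    if not records:
        return pd.DataFrame(columns=list(META_COLUMNS))
    ref = (records[0].config.palette, records[0].config.toolset)
    rows = []
    seen = set()
    for rec in records:
        if (rec.config.palette, rec.config.toolset) != ref:
            raise ValueError("all sessions must share the studio config")
        key = (rec.meta.subject, rec.meta.task)
        if key in seen:
            raise ValueError(f"duplicate (subject, task) pair: {key}")
        seen.add(key)
        row = {"subject": rec.meta.subject, "task": rec.meta.task,
               **rec.meta.groups,
               **compute_metrics(rec, use_trace=use_trace).flatten()}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-sample machinery


@dataclass(frozen=True)
class TwoSample:
    t_stat: float
    t_p: float
    rank_stat: float  # Mann-Whitney U of the first group
    rank_p: float
    degenerate: bool


def two_sample_tests(a: np.ndarray, b: np.ndarray,
                     equal_var: bool = False) -> TwoSample:
    """Welch t-test (pooled-variance optional) and rank-sum on two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    degenerate = False
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        degenerate = True
        if np.mean(a) == np.mean(b):
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, np.mean(a) - np.mean(b))
            t_p = 0.0
    else:
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, t_p = float(t_stat), float(t_p)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        rank_stat, rank_p = u, 1.0
    else:
        method = ("exact" if not has_ties and len(pooled) <= 20
                  else "asymptotic")
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method=method, use_continuity=False)
        rank_stat, rank_p = float(res.statistic), float(res.pvalue)
    return TwoSample(t_stat, t_p, rank_stat, rank_p, degenerate)


@dataclass(frozen=True)
class CohortResult:
    """One metric × scope group comparison."""

    metric: str
    group_label: str
    scope: Optional[tuple[str, ...]]  # None = all tasks pooled
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    median_a: float
    median_b: float
    t_stat: float
    t_p: float
    rank_stat: float
    rank_p: float
    alpha: float
    significant_t: bool
    significant_rank: bool
    significant_both: bool
    degenerate: bool = False
    valid: bool = True

    def as_row(self) -> dict:
        d = self.__dict__.copy()
        d["scope"] = "all" if self.scope is None else "+".join(self.scope)
        return d


def _na_result(metric, group_label, scope, groups, alpha) -> CohortResult:
    ga = groups[0] if len(groups) > 0 else ""
    gb = groups[1] if len(groups) > 1 else ""
    nan = float("nan")
    return CohortResult(metric, group_label, scope, ga, gb, 0, 0,
                        nan, nan, nan, nan, nan, nan, nan, nan, nan, nan,
                        alpha, False, False, False, degenerate=True,
                        valid=False)


def compare_groups(frame: pd.DataFrame, metric: str, group_label: str,
                   scope: str | Sequence[str] | None = None,
                   alpha: float = 0.05,
                   equal_var: bool = False) -> CohortResult:
    """Compare one metric between the two groups of ``group_label``.

    ``scope`` restricts to a task (or several, pooled as independent
    observations); None pools every task.  Groups smaller than 2 yield an
    NA-flagged result rather than an error so that metric scans stay
    total.
    """
    scope_t = ((scope,) if isinstance(scope, str)
               else tuple(scope) if scope is not None else None)
    sub = frame if scope_t is None else frame[frame["task"].isin(scope_t)]
    sub = sub.dropna(subset=[metric, group_label])
    groups = sorted(sub[group_label].unique())
    if len(groups) != 2:
        return _na_result(metric, group_label, scope_t, groups, alpha)
    a = sub.loc[sub[group_label] == groups[0], metric].to_numpy(float)
    b = sub.loc[sub[group_label] == groups[1], metric].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        return _na_result(metric, group_label, scope_t, groups, alpha)
    ts = two_sample_tests(a, b, equal_var=equal_var)
    sig_t = bool(ts.t_p < alpha)
    sig_rank = bool(ts.rank_p < alpha)
    return CohortResult(
        metric=metric, group_label=group_label, scope=scope_t,
        group_a=groups[0], group_b=groups[1], n_a=len(a), n_b=len(b),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sem_a=float(np.std(a, ddof=1) / math.sqrt(len(a))),
        sem_b=float(np.std(b, ddof=1) / math.sqrt(len(b))),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        t_stat=ts.t_stat, t_p=ts.t_p,
        rank_stat=ts.rank_stat, rank_p=ts.rank_p,
        alpha=alpha, significant_t=sig_t, significant_rank=sig_rank,
        significant_both=sig_t and sig_rank, degenerate=ts.degenerate,
    )


def scan_metrics(frame: pd.DataFrame, group_label: str,
                 scopes: Sequence[str | Sequence[str] | None] | None = None,
                 alpha: float = 0.05,
                 metrics: Sequence[str] | None = None,
                 equal_var: bool = False) -> list[CohortResult]:
    """Run compare_groups for every metric × scope.

    ``metrics`` defaults to every numeric column that is not metadata;
    ``scopes`` defaults to the pooled scope only.  The subset significant
    under both tests is ``[r for r in results if r.significant_both]``.
    """
    if metrics is None:
        skip = set(META_COLUMNS) | {group_label}
        metrics = [c for c in frame.columns
                   if c not in skip and pd.api.types.is_numeric_dtype(frame[c])]
    if scopes is None:
        scopes = [None]
    return [compare_groups(frame, m, group_label, scope=s, alpha=alpha,
                           equal_var=equal_var)
            for m in metrics for s in scopes]


def results_frame(results: Sequence[CohortResult],
                  fdr: bool = False) -> pd.DataFrame:
    """Tabulate scan results; ``fdr=True`` adds Benjamini–Hochberg
    q-value columns (bh_q_t, bh_q_rank) as an extension beyond the raw
    per-test p-values."""
    df = pd.DataFrame([r.as_row() for r in results])
    if fdr and len(df):
        for col, out in (("t_p", "bh_q_t"), ("rank_p", "bh_q_rank")):
            p = df[col].to_numpy(float)
            ok = np.isfinite(p)
            q = np.full_like(p, np.nan)
            if ok.sum():
                q[ok] = stats.false_discovery_control(p[ok], method="bh")
            df[out] = q
    return df


def significant_subset(results: Sequence[CohortResult]) -> list[CohortResult]:
    return [r for r in results if r.significant_both]
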