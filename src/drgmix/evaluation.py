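"""Case-mix evaluation: per-group statistics, ceilings, overuse, savings.

For each DRG group the descriptive block is mean, sample SD, coefficient of
variation CV = SD/mean, linear-interpolation quartiles, IQR = P75 - P25,
case-mix weight = group mean / overall mean, and the boxplot-rule payment
ceiling

    upper_limit = P75 + 1.5 * IQR.

A case costing strictly more than its group's ceiling is an "overuse" case;
the overuse rate is the percentage of such cases, and ``times`` is the
ratio of the overuse-subgroup mean to the normal-subgroup mean.  Under a
full-control payment policy every overuse case would be reimbursed at most
at the ceiling, so the projected saving is

    sum_g n_overuse_g * (mean_overuse_g - upper_limit_g),

clamped at zero per group.  Scheme-level quality is summarized by the
number of groups, enrollment rate, the share of groups with CV below 1 and
below 0.8, and the reduction in variance

    RIV = (Var_total - sum_g (n_g/N) Var_g) / Var_total

(population variances; bounded in [0, 100] when reported as a percent).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import N_CC_SLOTS

__all__ = [
    "GroupStats",
    "OveruseRow",
    "SchemeReport",
    "group_stats",
    "group_stats_frame",
    "scheme_riv",
    "overuse_partition",
    "overuse_report",
    "projected_savings",
    "scheme_report",
    "lower_median",
    "subgroup_descriptives",
    "evaluate_grouping",
]


@dataclass
class GroupStats:
    group_id: int | str
    n: int
    mean: float
    sd: float
    cv: float
    p25: float
    p75: float
    iqr: float
    weight: float
    upper_limit: float


def group_stats(costs: Sequence[float], overall_mean: float, group_id=0) -> GroupStats:
    """Descriptive block for one group's costs.

    SD uses the n-1 denominator (0 for a single case); quartiles use
    linear interpolation between order statistics.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ValueError("costs must be non-empty")
    if overall_mean <= 0:
        raise ValueError("overall_mean must be > 0")
    mean = float(np.mean(costs))
    sd = float(np.std(costs, ddof=1)) if costs.size > 1 else 0.0
    p25 = float(np.percentile(costs, 25))
    p75 = float(np.percentile(costs, 75))
    iqr = p75 - p25
    return GroupStats(
        group_id=group_id,
        n=int(costs.size),
        mean=mean,
        sd=sd,
        cv=sd / mean if mean > 0 else float("nan"),
        p25=p25,
        p75=p75,
        iqr=iqr,
        weight=mean / overall_mean,
        upper_limit=p75 + 1.5 * iqr,
    )


def group_stats_frame(
    df: pd.DataFrame, group_col: str = "group_id", cost_col: str = "cost"
) -> pd.DataFrame:
    """Per-group :func:`group_stats` over a grouped claims table.

    The weight denominator is the grouped cohort's own mean cost, so the
    case-mix identity sum_g (n_g/N) * weight_g = 1 holds exactly.
    """
    overall_mean = float(df[cost_col].mean())
    rows = [
        asdict(group_stats(sub[cost_col].to_numpy(), overall_mean, group_id=gid))
        for gid, sub in df.groupby(group_col, sort=True)
    ]
    return pd.DataFrame(rows)


def scheme_riv(groups: Sequence[Sequence[float]], all_costs: Sequence[float]) -> float:
    """Reduction in variance of a grouping, as a percentage in [0, 100].

    ``groups`` must partition ``all_costs``; population variances.  Zero by
    convention when the total variance is zero.
    """
    all_costs = np.asarray(all_costs, dtype=float)
    sizes = sum(len(g) for g in groups)
    if sizes != all_costs.size:
        raise ValueError("groups must partition the cohort")
    var_total = float(np.var(all_costs))
    if var_total == 0.0:
        return 0.0
    n = all_costs.size
    within = sum(len(g) / n * float(np.var(np.asarray(g, dtype=float))) for g in groups)
    return 100.0 * (var_total - within) / var_total


@dataclass
class OveruseRow:
    group_id: int | str
    n_total: int
    n_normal: int
    n_overuse: int
    overuse_rate: float  # percent
    mean_normal: float
    mean_overuse: float
    times: float  # mean_overuse / mean_normal; NaN when undefined
    los_median_normal: float
    los_median_overuse: float
    cc_mean_normal: float
    cc_mean_overuse: float
    saving: float


def overuse_partition(costs: Sequence[float], upper_limit: float):
    """Split one group's costs at its ceiling (strictly above = overuse).

    Returns ``(normal_mask, n_normal, n_overuse, rate_pct, mean_normal,
    mean_overuse, times)`` with NaN means/ratio where a side is empty.
    """
    costs = np.asarray(costs, dtype=float)
    over = costs > upper_limit
    n_over = int(over.sum())
    n_norm = int(costs.size - n_over)
    mean_norm = float(np.mean(costs[~over])) if n_norm else float("nan")
    mean_over = float(np.mean(costs[over])) if n_over else float("nan")
    times = mean_over / mean_norm if n_norm and n_over and mean_norm > 0 else float("nan")
    rate = 100.0 * n_over / costs.size if costs.size else 0.0
    return ~over, n_norm, n_over, rate, mean_norm, mean_over, times


def lower_median(values: Sequence[float]) -> float:
    """Median taking the lower of the two central order statistics."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        return float("nan")
    return float(values[(values.size - 1) // 2])


def _cc_counts(df: pd.DataFrame) -> np.ndarray:
    cols = [f"cc{i}" for i in range(1, N_CC_SLOTS + 1)]
    present = [c for c in cols if c in df.columns]
    if not present:
        return np.zeros(len(df))
    sub = df[present].fillna("")
    return (sub != "").to_numpy().sum(axis=1)


def subgroup_descriptives(df: pd.DataFrame, normal_mask: np.ndarray):
    """LOS medians (lower median) and mean CC counts, normal vs overuse."""
    counts = _cc_counts(df)
    los = df["los"].to_numpy(dtype=float)
    norm, over = normal_mask, ~normal_mask
    return (
        lower_median(los[norm]) if norm.any() else float("nan"),
        lower_median(los[over]) if over.any() else float("nan"),
        float(np.mean(counts[norm])) if norm.any() else float("nan"),
        float(np.mean(counts[over])) if over.any() else float("nan"),
    )


def overuse_report(
    df: pd.DataFrame,
    stats: pd.DataFrame,
    group_col: str = "group_id",
    cost_col: str = "cost",
) -> pd.DataFrame:
    """Per-group overuse partition with LOS/CC descriptives and savings."""
    limits = dict(zip(stats["group_id"], stats["upper_limit"]))
    rows = []
    for gid, sub in df.groupby(group_col, sort=True):
        costs = sub[cost_col].to_numpy(dtype=float)
        limit = limits[gid]
        normal_mask, n_norm, n_over, rate, mean_norm, mean_over, times = overuse_partition(
            costs, limit
        )
        los_n, los_o, cc_n, cc_o = subgroup_descriptives(sub, normal_mask)
        saving = max(n_over * (mean_over - limit), 0.0) if n_over else 0.0
        rows.append(
            asdict(
                OveruseRow(
                    group_id=gid,
                    n_total=len(costs),
                    n_normal=n_norm,
                    n_overuse=n_over,
                    overuse_rate=rate,
                    mean_normal=mean_norm,
                    mean_overuse=mean_over,
                    times=times,
                    los_median_normal=los_n,
                    los_median_overuse=los_o,
                    cc_mean_normal=cc_n,
                    cc_mean_overuse=cc_o,
                    saving=saving,
                )
            )
        )
    return pd.DataFrame(rows)


def projected_savings(
    n_overuse: Sequence[int], mean_overuse: Sequence[float], upper_limit: Sequence[float]
) -> float:
    """Full-control saving: sum_g n_over * (mean_over - ceiling), >= 0 per group."""
    total = 0.0
    for n, m, u in zip(n_overuse, mean_overuse, upper_limit):
        if n > 0 and np.isfinite(m):
            total += max(n * (m - u), 0.0)
    return total


@dataclass
class SchemeReport:
    n_groups: int
    enrollment_rate: float  # percent
    pct_cv_lt_1: float
    pct_cv_lt_08: float
    riv_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def scheme_report(stats: pd.DataFrame, riv_pct: float, n_cohort: int | None = None) -> SchemeReport:
    """Scheme-level summary from the per-group stats table."""
    if len(stats) == 0:
        raise ValueError("at least one group required")
    cv = stats["cv"].to_numpy(dtype=float)
    n_enrolled = int(stats["n"].sum())
    enrollment = 100.0 * n_enrolled / n_cohort if n_cohort else 100.0
    return SchemeReport(
        n_groups=len(stats),
        enrollment_rate=enrollment,
        pct_cv_lt_1=100.0 * float(np.mean(cv < 1.0)),
        pct_cv_lt_08=100.0 * float(np.mean(cv < 0.8)),
        riv_pct=riv_pct,
    )


def evaluate_grouping(
    df: pd.DataFrame, group_ids: Sequence, cost_col: str = "cost"
) -> tuple[pd.DataFrame, pd.DataFrame, SchemeReport]:
    """Full evaluation of one grouping of a claims table.

    Returns ``(group stats, overuse report, scheme report)``.
    """
    work = df.copy()
    work["group_id"] = list(group_ids)
    stats = group_stats_frame(work, cost_col=cost_col)
    overuse = overuse_report(work, stats, cost_col=cost_col)
    costs = work[cost_col].to_numpy(dtype=float)
    parts = [g[cost_col].to_numpy(dtype=float) for _, g in work.groupby("group_id", sort=True)]
    report = scheme_report(stats, scheme_riv(parts, costs), n_cohort=len(work))
    return stats, overuse, report
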