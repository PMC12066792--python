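"""Published per-group result tables and the arithmetic re-check mode.

The study cohort behind the published grouping results is not publicly
available, but the published per-group tables (for both the benchmark
grouping and the two-stage grouping: enrollment, mean, SD, CV, IQR, P75,
weight, ceiling; and the overuse partitions with normal/overuse counts and
means) are fully self-consistent arithmetic.  This module ships a
transcription of those tables and recomputes every derivable quantity from
its primitive columns: ceilings from P75 and IQR, CVs from SD and mean,
weights from the group mean and the published overall mean cost of
1,564.342, overuse rates from the counts, "times" ratios from the subgroup
means, and the two projected full-control savings totals.

``tables_check`` is the package's desk-scale verification that the payment
arithmetic implemented in :mod:`drgmix.evaluation` reproduces the published
values exactly at their printed precision.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .evaluation import projected_savings

__all__ = [
    "OVERALL_MEAN_COST",
    "load_group_table",
    "load_overuse_table",
    "tables_check",
]

#: Published overall mean hospitalization cost of the cleaned cohort (USD).
OVERALL_MEAN_COST = 1_564.342

_GROUP_FILES = {"benchmark": "benchmark_groups.csv", "two_stage": "two_stage_groups.csv"}
_OVERUSE_FILES = {"benchmark": "benchmark_overuse.csv", "two_stage": "two_stage_overuse.csv"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("drgmix.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_group_table(scheme: str) -> pd.DataFrame:
    """Published per-group stats for ``"benchmark"`` or ``"two_stage"``."""
    return _read(_GROUP_FILES[scheme])


def load_overuse_table(scheme: str) -> pd.DataFrame:
    """Published per-group overuse partition for one scheme."""
    return _read(_OVERUSE_FILES[scheme])


def tables_check() -> dict:
    """Recompute every derivable quantity in the published tables.

    Returns a dict with, per scheme, the recomputed per-group columns
    (``upper_limit``, ``cv``, ``weight``, ``overuse_rate``, ``times``), the
    maximal absolute deviation of each from its published column, the
    projected savings total, and headline scheme-level summaries.  All
    recomputation starts from primitive columns only (counts, means, SD,
    P75, IQR) — never from the published value being checked.
    """
    out: dict = {"overall_mean": OVERALL_MEAN_COST, "schemes": {}}
    for scheme in ("benchmark", "two_stage"):
        groups = load_group_table(scheme)
        overuse = load_overuse_table(scheme)
        upper = groups["p75"] + 1.5 * groups["iqr"]
        cv = groups["sd"] / groups["mean"]
        weight = groups["mean"] / OVERALL_MEAN_COST
        rate = 100.0 * overuse["n_overuse"] / overuse["n_total"]
        times = overuse["mean_overuse"] / overuse["mean_normal"]
        merged = overuse.merge(groups[["group_id", "upper_limit"]], on="group_id")
        savings = projected_savings(
            merged["n_overuse"], merged["mean_overuse"], merged["upper_limit"]
        )
        out["schemes"][scheme] = {
            "n_groups": int(len(groups)),
            "upper_limit": upper.round(2).tolist(),
            "cv": cv.round(2).tolist(),
            "weight": weight.round(2).tolist(),
            "overuse_rate": rate.round(2).tolist(),
            "times": times.round(2).tolist(),
            "savings": savings,
            "savings_million": savings / 1e6,
            "pct_cv_lt_1": 100.0 * float(np.mean(cv.round(2) < 1.0)),
            "pct_cv_lt_08": 100.0 * float(np.mean(cv.round(2) < 0.8)),
            "max_dev_upper_limit": float((upper - groups["upper_limit"]).abs().max()),
            "max_dev_cv": float((cv.round(2) - groups["cv"]).abs().max()),
            "max_dev_weight": float((weight.round(2) - groups["weight"]).abs().max()),
            "max_dev_overuse_rate": float((rate.round(2) - overuse["overuse_rate"]).abs().max()),
            "max_dev_times": float((times.round(2) - overuse["times"]).abs().max()),
        }
    return out
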