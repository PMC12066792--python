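"""Rule-table-driven benchmark grouper.

Emulates a national-standard DRG grouper as data, not code: a user-supplied
lookup assigns each CC code a severity (MCC / CC / nonCC), a patient's
severity is the maximum over their CC codes, and an ordered first-match-wins
rule list maps (severity, hospital level, insurance, ..., main-diagnosis
prefix) to a group label, with a guaranteed default.  The actual national
grouping standard's rule content is supplied by the user as such a file;
nothing here hard-codes it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .io import N_CC_SLOTS
from .stage1 import add_strata_columns

__all__ = [
    "BENCHMARK_SEVERITIES",
    "Rule",
    "RuleTable",
    "load_rule_table",
    "record_severity",
    "apply_rules",
    "RuleTableGrouper",
]

logger = logging.getLogger(__name__)

BENCHMARK_SEVERITIES = ("MCC", "CC", "nonCC")
_SEV_RANK = {"MCC": 0, "CC": 1, "nonCC": 2}

# Fields a rule predicate may constrain. "main_dx_prefix" matches the start
# of the main diagnosis code; all others are exact-level (or any-of-list).
RULE_FIELDS = (
    "severity",
    "hospital_level",
    "insurance",
    "sex",
    "charge_level",
    "age_bin",
    "los_bin",
    "main_dx_prefix",
)


@dataclass(frozen=True)
class Rule:
    when: dict
    label: str

    def matches(self, row: dict) -> bool:
        for fld, want in self.when.items():
            if fld == "main_dx_prefix":
                prefixes = want if isinstance(want, (list, tuple)) else [want]
                if not any(str(row["main_dx"]).startswith(str(p)) for p in prefixes):
                    return False
            else:
                allowed = want if isinstance(want, (list, tuple)) else [want]
                if row[fld] not in [str(a) for a in allowed]:
                    return False
        return True


@dataclass
class RuleTable:
    cc_lookup: dict[str, str] = field(default_factory=dict)
    rules: list[Rule] = field(default_factory=list)
    default_label: str = "UNGROUPED"

    def severity_of(self, code: str) -> str:
        return self.cc_lookup.get(code, "nonCC")

    def check_disjoint(self) -> bool:
        """Warn when two rules could both match (order then matters)."""
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1 :]:
                clash = True
                for fld in set(a.when) & set(b.when):
                    av = a.when[fld] if isinstance(a.when[fld], (list, tuple)) else [a.when[fld]]
                    bv = b.when[fld] if isinstance(b.when[fld], (list, tuple)) else [b.when[fld]]
                    if not set(map(str, av)) & set(map(str, bv)):
                        clash = False
                        break
                if clash and a.label != b.label:
                    logger.warning(
                        "rules for %r and %r overlap; evaluation order decides", a.label, b.label
                    )
                    return False
        return True


def _load_cc_lookup(obj, base: Path) -> dict[str, str]:
    if isinstance(obj, str):  # path to a code,severity CSV
        path = base / obj if not Path(obj).is_absolute() else Path(obj)
        df = pd.read_csv(path, dtype=str)
        conflicts = sorted(
            code
            for code, grp in df.groupby("code")["severity"]
            if grp.nunique() > 1
        )
        if conflicts:
            raise ValueError(f"conflicting severities for code(s): {conflicts}")
        obj = dict(zip(df["code"], df["severity"]))
    bad = {c: s for c, s in obj.items() if s not in BENCHMARK_SEVERITIES}
    if bad:
        raise ValueError(f"unknown severity value(s): {bad}")
    return dict(obj)


def load_rule_table(path) -> RuleTable:
    """Read a YAML/JSON rule file.

    Layout: ``cc_lookup`` (inline mapping, or a relative path to a
    ``code,severity`` CSV), ordered ``rules`` (each ``when`` + ``label``),
    and ``default_label``.  Unknown severities and unknown predicate fields
    are rejected; duplicate codes with conflicting severities are reported.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
    lookup = _load_cc_lookup(raw.get("cc_lookup", {}), path.parent)
    rules = []
    for entry in raw.get("rules", []):
        when = dict(entry.get("when", {}))
        unknown = set(when) - set(RULE_FIELDS)
        if unknown:
            raise ValueError(f"unknown rule field(s): {sorted(unknown)}")
        rules.append(Rule(when=when, label=str(entry["label"])))
    table = RuleTable(
        cc_lookup=lookup, rules=rules, default_label=str(raw.get("default_label", "UNGROUPED"))
    )
    table.check_disjoint()
    return table


def record_severity(cc_codes, table: RuleTable) -> str:
    """Patient severity: maximum severity over occupied CC slots."""
    sev = "nonCC"
    for code in cc_codes:
        if code and _SEV_RANK[table.severity_of(code)] < _SEV_RANK[sev]:
            sev = table.severity_of(code)
    return sev


def apply_rules(row, table: RuleTable) -> str:
    """First matching rule's label; the default label guarantees totality."""
    cc = [row[f"cc{i}"] for i in range(1, N_CC_SLOTS + 1)]
    ctx = dict(row)
    ctx["severity"] = record_severity(cc, table)
    for rule in table.rules:
        if rule.matches(ctx):
            return rule.label
    return table.default_label


class RuleTableGrouper(BaseEstimator):
    """Benchmark grouper over a fixed rule table (fit is a no-op check)."""

    def __init__(self, table: RuleTable | None = None):
        self.table = table

    def fit(self, X=None, y=None) -> "RuleTableGrouper":
        if self.table is None:
            raise ValueError("a RuleTable is required")
        self.table_ = self.table
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "table_")
        df = add_strata_columns(X)
        return np.asarray([apply_rules(row, self.table_) for _, row in df.iterrows()], dtype=object)
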