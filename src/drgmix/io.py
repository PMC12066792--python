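"""Claim records, delimited-file I/O, and pre-analysis cleaning.

A hospitalization claim is one row: demographics, insurance type, hospital
and charge level, length of stay (LOS), total cost, an ICD-10 main
diagnosis, and up to seven ICD-10 secondary-diagnosis codes (comorbidities
and complications, "CCs").  The seven CC columns are positional: slot ``i``
feeds the ``i``-th cost-regression model downstream, so empty slots are
kept as empty strings rather than compacted away.

Cleaning applies the standard claims filters — completeness, a length-of-
stay ceiling, and a reimbursement-cap cost ceiling — and returns an audit
trail whose counts always reconcile with the input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SEXES",
    "INSURANCE_TYPES",
    "HOSPITAL_LEVELS",
    "CHARGE_LEVELS",
    "AGE_BINS",
    "LOS_BINS",
    "N_CC_SLOTS",
    "CLAIM_COLUMNS",
    "ClaimRecord",
    "CleaningConfig",
    "CleaningAudit",
    "SchemaError",
    "RowError",
    "read_claims",
    "write_claims",
    "claims_to_frame",
    "frame_to_claims",
    "clean_claims",
    "age_bin",
    "los_bin",
]

SEXES = ("male", "female")
INSURANCE_TYPES = ("urban_employee", "urban_rural_resident")
HOSPITAL_LEVELS = ("primary", "secondary", "tertiary")
# Six payment/charge grades; the two "tertiary_b_*" grades are the +/-10%
# adjusted variants of the grade-B tertiary rate.
CHARGE_LEVELS = (
    "tertiary_a",
    "tertiary_b",
    "secondary_a",
    "secondary_b",
    "tertiary_b_up",
    "tertiary_b_down",
)
# Age bins follow the cohort's structure: a young minority, then three
# elderly strata.  Order matters: index 0 is the reference level downstream.
AGE_BINS = ("le45", "45to65", "65to75", "75to85", "ge85")
LOS_BINS = ("lt9", "9to12", "gt12")

N_CC_SLOTS = 7

CLAIM_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "insurance",
    "hospital_level",
    "charge_level",
    "los",
    "cost",
    "main_dx",
] + [f"cc{i}" for i in range(1, N_CC_SLOTS + 1)]

_ENUM_DOMAINS = {
    "sex": SEXES,
    "insurance": INSURANCE_TYPES,
    "hospital_level": HOSPITAL_LEVELS,
    "charge_level": CHARGE_LEVELS,
}

_REQUIRED_DEFAULT = (
    "patient_id",
    "sex",
    "age",
    "insurance",
    "hospital_level",
    "charge_level",
    "los",
    "cost",
    "main_dx",
)


class SchemaError(ValueError):
    """A claims file is missing a required column."""


class RowError(ValueError):
    """A data row holds an unparseable enum or number (reports the line)."""


def age_bin(age: int) -> str:
    """Map an age in years onto the cohort's five age strata."""
    if age <= 45:
        return "le45"
    if age < 65:
        return "45to65"
    if age < 75:
        return "65to75"
    if age < 85:
        return "75to85"
    return "ge85"


def los_bin(los: int) -> str:
    """Map a length of stay in days onto the three LOS strata."""
    if los < 9:
        return "lt9"
    if los <= 12:
        return "9to12"
    return "gt12"


@dataclass
class ClaimRecord:
    """One hospitalization.

    ``cc_codes`` is always a length-7 list; slot ``i`` (1-based) is entry
    ``cc_codes[i-1]`` and an empty string marks an unused slot.  Fields may
    be ``None`` (an incomplete record): incomplete records survive parsing
    and are dropped — and counted — by :func:`clean_claims`.
    """

    patient_id: str | None
    sex: str | None
    age: int | None
    insurance: str | None
    hospital_level: str | None
    charge_level: str | None
    los: int | None
    cost: float | None
    main_dx: str | None
    cc_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cc_codes) > N_CC_SLOTS:
            raise ValueError(
                f"at most {N_CC_SLOTS} CC codes allowed, got {len(self.cc_codes)}"
            )
        self.cc_codes = [str(c) if c else "" for c in self.cc_codes]
        self.cc_codes += [""] * (N_CC_SLOTS - len(self.cc_codes))
        for name, domain in _ENUM_DOMAINS.items():
            value = getattr(self, name)
            if value is not None and value not in domain:
                raise ValueError(f"{name}={value!r} not in {domain}")
        for name in ("age", "los"):
            value = getattr(self, name)
            if value is not None:
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value}")
                setattr(self, name, int(value))
        if self.cost is not None:
            if self.cost < 0:
                raise ValueError(f"cost must be >= 0, got {self.cost}")
            self.cost = float(self.cost)

    @property
    def n_ccs(self) -> int:
        """Number of occupied CC slots."""
        return sum(1 for c in self.cc_codes if c)

    def is_complete(self, required: Sequence[str] = _REQUIRED_DEFAULT) -> bool:
        for name in required:
            value = getattr(self, name)
            if value is None or value == "":
                return False
        return True


@dataclass
class CleaningConfig:
    """Cleaning filters: completeness, LOS ceiling, and cost cap.

    The defaults encode a 60-day stay ceiling and an annual reimbursement
    cap of 22,189 currency units.  Both comparisons are strict: a stay of
    exactly ``max_los`` days or a cost exactly at ``cost_cap`` is kept.
    """

    max_los: int = 60
    cost_cap: float = 22_189.0
    required_fields: tuple[str, ...] = _REQUIRED_DEFAULT

    def __post_init__(self) -> None:
        if self.max_los <= 0:
            raise ValueError("max_los must be > 0")
        if self.cost_cap <= 0:
            raise ValueError("cost_cap must be > 0")


@dataclass
class CleaningAudit:
    """Drop counts per rule; always reconciles with the input size."""

    n_input: int
    n_dropped_incomplete: int
    n_dropped_los: int
    n_dropped_cost: int
    n_output: int

    def __post_init__(self) -> None:
        drops = self.n_dropped_incomplete + self.n_dropped_los + self.n_dropped_cost
        if self.n_output != self.n_input - drops:
            raise ValueError("audit counts do not reconcile")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def clean_claims(
    records: Iterable[ClaimRecord], config: CleaningConfig | None = None
) -> tuple[list[ClaimRecord], CleaningAudit]:
    """Apply the cleaning filters and count what each rule removed.

    A record violating several rules is counted once, under the first rule
    in the order incomplete -> LOS -> cost, so the audit is well defined.
    Cleaning never raises on content; it drops and counts.
    """
    config = config or CleaningConfig()
    kept: list[ClaimRecord] = []
    n_incomplete = n_los = n_cost = 0
    records = list(records)
    for rec in records:
        if not rec.is_complete(config.required_fields):
            n_incomplete += 1
        elif rec.los > config.max_los:
            n_los += 1
        elif rec.cost > config.cost_cap:
            n_cost += 1
        else:
            kept.append(rec)
    audit = CleaningAudit(
        n_input=len(records),
        n_dropped_incomplete=n_incomplete,
        n_dropped_los=n_los,
        n_dropped_cost=n_cost,
        n_output=len(kept),
    )
    return kept, audit


# ---------------------------------------------------------------------------
# CSV round trip


def _parse_row(row: pd.Series, line_no: int) -> ClaimRecord:
    def opt_str(name: str) -> str | None:
        v = row[name]
        if pd.isna(v) or v == "":
            return None
        return str(v)

    def opt_num(name: str, cast) -> float | int | None:
        v = row[name]
        if pd.isna(v) or v == "":
            return None
        try:
            return cast(v)
        except (TypeError, ValueError) as exc:
            raise RowError(f"line {line_no}: bad value {v!r} for {name}") from exc

    cc = [opt_str(f"cc{i}") or "" for i in range(1, N_CC_SLOTS + 1)]
    try:
        return ClaimRecord(
            patient_id=opt_str("patient_id"),
            sex=opt_str("sex"),
            age=opt_num("age", int),
            insurance=opt_str("insurance"),
            hospital_level=opt_str("hospital_level"),
            charge_level=opt_str("charge_level"),
            los=opt_num("los", int),
            cost=opt_num("cost", float),
            main_dx=opt_str("main_dx"),
            cc_codes=cc,
        )
    except ValueError as exc:
        raise RowError(f"line {line_no}: {exc}") from exc


def read_claims(path: str | Path) -> list[ClaimRecord]:
    """Read a UTF-8 claims CSV; row order is preserved.

    Raises :class:`SchemaError` naming any missing column and
    :class:`RowError` with the 1-based data line number for bad values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return [_parse_row(row, i + 1) for i, (_, row) in enumerate(df.iterrows())]


def claims_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    """Tabular view of claims; the canonical in-memory container downstream."""
    rows = []
    for rec in records:
        row = {f.name: getattr(rec, f.name) for f in dc_fields(rec) if f.name != "cc_codes"}
        for i in range(N_CC_SLOTS):
            row[f"cc{i + 1}"] = rec.cc_codes[i]
        rows.append(row)
    df = pd.DataFrame(rows, columns=CLAIM_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=CLAIM_COLUMNS)
    return df


def frame_to_claims(df: pd.DataFrame) -> list[ClaimRecord]:
    return [
        ClaimRecord(
            patient_id=row["patient_id"],
            sex=row["sex"],
            age=row["age"],
            insurance=row["insurance"],
            hospital_level=row["hospital_level"],
            charge_level=row["charge_level"],
            los=row["los"],
            cost=row["cost"],
            main_dx=row["main_dx"],
            cc_codes=[row[f"cc{i}"] for i in range(1, N_CC_SLOTS + 1)],
        )
        for _, row in df.iterrows()
    ]


def write_claims(records: Iterable[ClaimRecord], path: str | Path) -> None:
    """Write claims as UTF-8 CSV with empty cells for unused CC slots."""
    claims_to_frame(records).to_csv(path, index=False)
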