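"""Stage 1: regression-based severity tiering of comorbidities/complications.

Seven ordinary-least-squares cost regressions are fitted, one per secondary-
diagnosis slot ``i``.  Model ``i`` regresses raw hospitalization cost on a
0/1 indicator for every distinct CC code observed in slot ``i`` plus one-hot
encoded control variables (sex, age stratum, LOS stratum, hospital level,
insurance type, charge level):

    y = sum_j beta_ij * x_ij + sum_n gamma_n * control_n + e

CC codes significant (p < alpha) in at least one model are ranked within
each model by coefficient, descending, and tiered by rank percentile: the
top 30% are major (MCC), ranks 30-60% moderate (mCC), the rest non-CC.  A
code reaching different tiers in different models keeps its most severe
tier.  Patients are then typed by their worst CC: any MCC -> type I, else
any mCC -> type II, else type III.

The response is raw cost, not log cost: the ranking rule compares
currency-scale coefficients, so the regression must produce them.  A
log-response option exists for sensitivity analyses but is off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .io import (
    AGE_BINS,
    CHARGE_LEVELS,
    CLAIM_COLUMNS,
    HOSPITAL_LEVELS,
    INSURANCE_TYPES,
    LOS_BINS,
    N_CC_SLOTS,
    SEXES,
    age_bin,
    claims_to_frame,
    los_bin,
)

__all__ = [
    "TIERS",
    "NoCCsInSlotError",
    "RegressionFit",
    "SeverityEntry",
    "SeverityTable",
    "build_design",
    "fit_cost_regression",
    "select_and_rank",
    "tier_ccs",
    "assign_patient_type",
    "CCSeverityClassifier",
]

logger = logging.getLogger(__name__)

TIERS = ("MCC", "mCC", "nonCC")
_TIER_RANK = {"MCC": 0, "mCC": 1, "nonCC": 2}
PATIENT_TYPES = ("I", "II", "III")

# Reference levels dropped from the one-hot encoding, one per control.
CONTROL_REFERENCE = {
    "sex": "male",
    "insurance": "urban_employee",
    "hospital_level": "primary",
    "charge_level": "tertiary_b_down",
    "age_bin": AGE_BINS[0],
    "los_bin": LOS_BINS[0],
}
_CONTROL_DOMAINS = {
    "sex": SEXES,
    "insurance": INSURANCE_TYPES,
    "hospital_level": HOSPITAL_LEVELS,
    "charge_level": CHARGE_LEVELS,
    "age_bin": AGE_BINS,
    "los_bin": LOS_BINS,
}


class NoCCsInSlotError(ValueError):
    """Raised when a diagnosis slot is empty for every claim in the cohort."""


@dataclass
class RegressionFit:
    """One fitted slot model: CC terms, control terms, fit diagnostics."""

    model_index: int
    cc_terms: list[tuple[str, float, float]]  # (code, coefficient, p-value)
    control_terms: list[tuple[str, float]]
    residual_se: float
    n_obs: int
    cc_standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def n_cc_terms(self) -> int:
        return len(self.cc_terms)


@dataclass(frozen=True)
class SeverityEntry:
    tier: str
    model_index: int
    coefficient: float
    p_value: float


@dataclass
class SeverityTable:
    """CC code -> severity tier, with the model evidence behind each tier.

    Only codes significant in at least one model appear; absent codes are
    treated as non-CC by :func:`assign_patient_type`.
    """

    entries: dict[str, SeverityEntry] = field(default_factory=dict)
    alpha: float = 0.05
    cut_major: float = 0.30
    cut_moderate: float = 0.60

    def tier_of(self, code: str) -> str:
        entry = self.entries.get(code)
        return entry.tier if entry is not None else "nonCC"

    def codes_with_tier(self, tier: str) -> list[str]:
        return sorted(c for c, e in self.entries.items() if e.tier == tier)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": code,
                "tier": e.tier,
                "model_index": e.model_index,
                "coefficient": e.coefficient,
                "p_value": e.p_value,
            }
            for code, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["code", "tier", "model_index", "coefficient", "p_value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, alpha: float = 0.05) -> "SeverityTable":
        df = pd.read_csv(path, float_precision="round_trip")
        entries = {
            str(r["code"]): SeverityEntry(
                tier=str(r["tier"]),
                model_index=int(r["model_index"]),
                coefficient=float(r["coefficient"]),
                p_value=float(r["p_value"]),
            )
            for _, r in df.iterrows()
        }
        return cls(entries=entries, alpha=alpha)


def add_strata_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``age_bin`` and ``los_bin`` columns derived from age and LOS."""
    out = df.copy()
    out["age_bin"] = [age_bin(a) for a in out["age"]]
    out["los_bin"] = [los_bin(v) for v in out["los"]]
    return out


def _as_frame(claims) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
        if missing:
            raise ValueError(f"claims frame missing column(s): {missing}")
        return claims
    return claims_to_frame(claims)


def build_design(claims, model_index: int) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Design matrix for slot model ``model_index`` (1-based).

    Returns ``(X, y, cc_codes)`` where X holds one 0/1 indicator per
    distinct CC code observed in the slot (columns ``cc_<code>``), one-hot
    control dummies against the declared reference levels, and a constant.
    """
    if not 1 <= model_index <= N_CC_SLOTS:
        raise ValueError(f"model_index must be in 1..{N_CC_SLOTS}")
    df = add_strata_columns(_as_frame(claims))
    slot = df[f"cc{model_index}"].fillna("").astype(str)
    codes = sorted(c for c in slot.unique() if c)
    if not codes:
        raise NoCCsInSlotError(f"no CC codes observed in slot {model_index}")
    X = pd.DataFrame(index=df.index)
    for code in codes:
        X[f"cc_{code}"] = (slot == code).astype(float)
    for control, domain in _CONTROL_DOMAINS.items():
        ref = CONTROL_REFERENCE[control]
        for level in domain:
            if level == ref:
                continue
            X[f"{control}_{level}"] = (df[control] == level).astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = df["cost"].astype(float)
    return X, y, codes


def _prune_rank_deficient(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant and aliased columns (never silently: logs a warning)."""
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        cols: list[str] = []
        for c in X.columns:
            trial = cols + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                cols.append(c)
            else:
                dropped.append(c)
        X = X[cols]
    if dropped:
        logger.warning("dropped %d constant/aliased design column(s): %s", len(dropped), dropped)
    return X


def fit_cost_regression(
    X: pd.DataFrame, y: pd.Series, model_index: int, log_response: bool = False
) -> RegressionFit:
    """OLS fit of one slot model; deterministic for fixed input.

    A constant response yields all-zero coefficients with p-values of 1 by
    convention.  Rank-deficient designs are pruned first, with a warning.
    """
    X = _prune_rank_deficient(X)
    yv = np.log(y.astype(float)) if log_response else y.astype(float)
    cc_cols = [c for c in X.columns if c.startswith("cc_")]
    ctl_cols = [c for c in X.columns if c != "const" and not c.startswith("cc_")]
    if float(np.var(yv)) == 0.0:
        return RegressionFit(
            model_index=model_index,
            cc_terms=[(c[3:], 0.0, 1.0) for c in cc_cols],
            control_terms=[(c, 0.0) for c in ctl_cols],
            residual_se=0.0,
            n_obs=len(yv),
        )
    res = sm.OLS(yv, X).fit()
    cc_terms = [(c[3:], float(res.params[c]), float(res.pvalues[c])) for c in cc_cols]
    control_terms = [(c, float(res.params[c])) for c in ctl_cols]
    return RegressionFit(
        model_index=model_index,
        cc_terms=cc_terms,
        control_terms=control_terms,
        residual_se=float(np.sqrt(res.scale)),
        n_obs=int(res.nobs),
        cc_standard_errors={c[3:]: float(res.bse[c]) for c in cc_cols},
    )


def select_and_rank(
    fits: list[RegressionFit], alpha: float = 0.05
) -> dict[int, list[tuple[str, float, float]]]:
    """Per-model ranked lists of significant CCs.

    Within each model, codes with p < alpha sorted by coefficient
    descending; coefficient ties broken by code, lexicographic.  A code may
    appear in several models' lists.
    """
    ranked: dict[int, list[tuple[str, float, float]]] = {}
    for fit in fits:
        sig = [(c, b, p) for (c, b, p) in fit.cc_terms if p < alpha]
        sig.sort(key=lambda t: (-t[1], t[0]))
        ranked[fit.model_index] = sig
    return ranked


def tier_ccs(
    ranked: dict[int, list[tuple[str, float, float]]],
    alpha: float = 0.05,
    cut_major: float = 0.30,
    cut_moderate: float = 0.60,
) -> SeverityTable:
    """Percentile-tier the ranked codes and merge across models.

    Per model with J significant codes, ranks 1..ceil(cut_major*J) are MCC,
    ranks up to ceil(cut_moderate*J) are mCC, the remainder non-CC.  A code
    tiered differently in different models takes its most severe tier; among
    models giving that tier, the one with the largest coefficient is kept as
    the table's evidence.
    """
    table = SeverityTable(alpha=alpha, cut_major=cut_major, cut_moderate=cut_moderate)
    for model_index in sorted(ranked):
        codes = ranked[model_index]
        J = len(codes)
        if J == 0:
            continue
        n_major = math.ceil(cut_major * J)
        n_moderate = math.ceil(cut_moderate * J)
        for rank, (code, coef, pval) in enumerate(codes, start=1):
            tier = "MCC" if rank <= n_major else ("mCC" if rank <= n_moderate else "nonCC")
            candidate = SeverityEntry(tier=tier, model_index=model_index, coefficient=coef, p_value=pval)
            current = table.entries.get(code)
            if (
                current is None
                or _TIER_RANK[candidate.tier] < _TIER_RANK[current.tier]
                or (
                    _TIER_RANK[candidate.tier] == _TIER_RANK[current.tier]
                    and candidate.coefficient > current.coefficient
                )
            ):
                table.entries[code] = candidate
    return table


def assign_patient_type(cc_codes, table: SeverityTable) -> str:
    """Type a patient by their worst CC: MCC -> I, mCC -> II, else III."""
    tiers = {table.tier_of(c) for c in cc_codes if c}
    if "MCC" in tiers:
        return "I"
    if "mCC" in tiers:
        return "II"
    return "III"


class CCSeverityClassifier(BaseEstimator):
    """Severity tiering of CC codes and patient typing, as an estimator.

    fit() learns a :class:`SeverityTable` from a claims table (list of
    :class:`~drgmix.io.ClaimRecord` or the equivalent DataFrame); predict()
    maps claims to patient types "I"/"II"/"III".

    Parameters
    ----------
    alpha : significance level for selecting CCs (raw p-values; no
        multiplicity correction, by design).
    cut_major, cut_moderate : rank-percentile boundaries of the MCC and mCC
        tiers.
    log_response : fit the regressions on log cost instead of raw cost
        (sensitivity option; ranking then uses log-scale coefficients).

    Attributes
    ----------
    fits_ : list of :class:`RegressionFit`, one per diagnosis slot (slots
        empty in the training cohort yield a fit with no CC terms).
    ranked_ : per-model ranked significant CC lists.
    severity_table_ : the merged :class:`SeverityTable`.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        cut_major: float = 0.30,
        cut_moderate: float = 0.60,
        log_response: bool = False,
    ):
        self.alpha = alpha
        self.cut_major = cut_major
        self.cut_moderate = cut_moderate
        self.log_response = log_response

    def fit(self, X, y=None) -> "CCSeverityClassifier":
        df = _as_frame(X)
        fits: list[RegressionFit] = []
        for i in range(1, N_CC_SLOTS + 1):
            try:
                design, cost, _ = build_design(df, i)
            except NoCCsInSlotError:
                fits.append(RegressionFit(i, [], [], 0.0, len(df)))
                continue
            fits.append(fit_cost_regression(design, cost, i, log_response=self.log_response))
        self.fits_ = fits
        self.ranked_ = select_and_rank(fits, alpha=self.alpha)
        self.severity_table_ = tier_ccs(
            self.ranked_, alpha=self.alpha, cut_major=self.cut_major, cut_moderate=self.cut_moderate
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Patient type per claim, from the fitted severity table."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "severity_table_")
        df = _as_frame(X)
        cc_cols = [f"cc{i}" for i in range(1, N_CC_SLOTS + 1)]
        return np.asarray(
            [
                assign_patient_type([row[c] for c in cc_cols], self.severity_table_)
                for _, row in df.iterrows()
            ],
            dtype=object,
        )
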