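"""Design construction, significance ranking, tier boundaries, patient typing."""

import numpy as np
import pandas as pd
import pytest

from drgmix.io import claims_to_frame
from drgmix.stage1 import (
    CCSeverityClassifier,
    NoCCsInSlotError,
    RegressionFit,
    SeverityEntry,
    SeverityTable,
    assign_patient_type,
    build_design,
    fit_cost_regression,
    select_and_rank,
    tier_ccs,
)
from .conftest import make_claim


class TestBuildDesign:
    def test_single_indicator(self):
        claims = [make_claim(cc_codes=["G97"]), make_claim(cc_codes=[])]
        X, y, codes = build_design(claims, 1)
        assert codes == ["G97"]
        assert X["cc_G97"].tolist() == [1.0, 0.0]
        assert y.tolist() == [1200.0, 1200.0]

    def test_slot_isolation(self):
        claims = [make_claim(cc_codes=["", "A10"]), make_claim(cc_codes=["B20", ""])]
        X, _, codes = build_design(claims, 1)
        assert codes == ["B20"] and "cc_A10" not in X.columns
        _, _, codes2 = build_design(claims, 2)
        assert codes2 == ["A10"]

    def test_empty_slot_raises(self):
        with pytest.raises(NoCCsInSlotError, match="slot 4"):
            build_design([make_claim(cc_codes=["G97"])], 4)

    def test_column_count_on_synthetic_cohort(self, cohort, cohort_frame):
        X, _, codes = build_design(cohort, 1)
        slot = cohort_frame["cc1"]
        distinct = {c for c in slot if c}
        # one indicator per distinct slot-1 code + control dummies + constant
        n_controls = (2 - 1) + (2 - 1) + (3 - 1) + (6 - 1) + (5 - 1) + (3 - 1)
        assert set(codes) == distinct
        assert X.shape[1] == len(distinct) + n_controls + 1


class TestRegression:
    def test_constant_response_convention(self):
        claims = [make_claim(cc_codes=["G97"]), make_claim()]
        X, y, _ = build_design(claims, 1)
        fit = fit_cost_regression(X, y, 1)
        assert fit.cc_terms == [("G97", 0.0, 1.0)]

    def test_planted_effect_recovered(self):
        # two-level design, known group difference, tiny noise
        rng = np.random.default_rng(0)
        claims = [
            make_claim(patient_id=str(i), cc_codes=["G97"] if i % 2 else [],
                       cost=2000.0 + (500.0 if i % 2 else 0.0) + rng.normal(0, 10))
            for i in range(400)
        ]
        X, y, _ = build_design(claims, 1)
        fit = fit_cost_regression(X, y, 1)
        (code, beta, p) = fit.cc_terms[0]
        assert code == "G97" and p < 0.05
        assert beta == pytest.approx(500.0, abs=5.0)


class TestSelectAndRank:
    def _fit(self, terms):
        return RegressionFit(model_index=1, cc_terms=terms, control_terms=[], residual_se=1.0, n_obs=10)

    def test_significance_filter_and_order(self):
        fit = self._fit([("A", 10.0, 0.01), ("B", 5.0, 0.20), ("C", 7.0, 0.04)])
        ranked = select_and_rank([fit], alpha=0.05)
        assert [c for c, _, _ in ranked[1]] == ["A", "C"]

    def test_all_insignificant_gives_empty(self):
        fit = self._fit([("A", 10.0, 0.5), ("B", 5.0, 0.9)])
        assert select_and_rank([fit])[1] == []

    def test_ranking_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        terms = [(f"C{i:02d}", float(rng.normal(0, 100)), float(rng.uniform(0, 0.04))) for i in range(25)]
        ranked = select_and_rank([self._fit(terms)])[1]
        oracle = sorted(terms, key=lambda t: (-t[1], t[0]))
        assert ranked == oracle


class TestTiering:
    def _ranked(self, n, model=1):
        return {model: [(f"C{i:02d}", float(n - i), 0.01) for i in range(n)]}

    @pytest.mark.parametrize(
        "J,n_mcc,n_mcc_plus_mcc",
        [(10, 3, 6), (7, 3, 5), (1, 1, 1), (2, 1, 2), (3, 1, 2)],
    )
    def test_ceiling_boundaries(self, J, n_mcc, n_mcc_plus_mcc):
        table = tier_ccs(self._ranked(J))
        tiers = [table.entries[f"C{i:02d}"].tier for i in range(J)]
        assert tiers.count("MCC") == n_mcc
        assert tiers.count("MCC") + tiers.count("mCC") == n_mcc_plus_mcc
        # the ranked order maps onto tiers monotonically
        assert tiers == sorted(tiers, key=["MCC", "mCC", "nonCC"].index)

    def test_cross_model_takes_most_severe(self):
        ranked = {
            2: [(f"X{i}", 10.0 - i, 0.01) for i in range(10)],  # X3.. -> mCC region
            5: [("X4", 99.0, 0.001)],  # J=1 -> MCC
        }
        table = tier_ccs(ranked)
        assert table.entries["X4"].tier == "MCC"
        assert table.entries["X4"].model_index == 5

    def test_partition_of_significant_set(self, cohort):
        clf = CCSeverityClassifier().fit(cohort)
        table = clf.severity_table_
        sig = {c for fit in clf.fits_ for c, _, p in fit.cc_terms if p < clf.alpha}
        assert set(table.entries) == sig
        assert sum(len(table.codes_with_tier(t)) for t in ("MCC", "mCC", "nonCC")) == len(sig)


class TestPatientType:
    TABLE = SeverityTable(
        entries={
            "M1": SeverityEntry("MCC", 1, 900.0, 0.001),
            "m1": SeverityEntry("mCC", 1, 400.0, 0.01),
        }
    )

    @pytest.mark.parametrize(
        "codes,expected",
        [
            (["M1"], "I"),
            (["m1", "M1"], "I"),
            (["m1"], "II"),
            (["m1", "unknown"], "II"),
            ([], "III"),
            (["unknown"], "III"),
        ],
    )
    def test_typing_rule(self, codes, expected):
        assert assign_patient_type(codes, self.TABLE) == expected

    def test_adding_mcc_never_lowers_priority(self):
        for codes in ([], ["m1"], ["unknown"]):
            before = assign_patient_type(codes, self.TABLE)
            after = assign_patient_type(codes + ["M1"], self.TABLE)
            assert after <= before  # "I" < "II" < "III" lexicographically

    def test_every_claim_gets_exactly_one_type(self, cohort, cohort_frame):
        clf = CCSeverityClassifier().fit(cohort_frame)
        types = clf.predict(cohort_frame)
        assert set(types) <= {"I", "II", "III"}
        assert len(types) == len(cohort)


def test_estimator_params_round_trip():
    clf = CCSeverityClassifier(alpha=0.01, cut_major=0.2)
    assert CCSeverityClassifier(**clf.get_params()).get_params() == clf.get_params()


def test_severity_table_csv_round_trip(tmp_path, cohort):
    clf = CCSeverityClassifier().fit(cohort)
    path = tmp_path / "severity.csv"
    clf.severity_table_.to_csv(path)
    loaded = SeverityTable.from_csv(path)
    assert loaded.entries == clf.severity_table_.entries
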