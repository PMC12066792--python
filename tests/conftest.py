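import pytest

from drgmix.io import ClaimRecord
from drgmix.synthetic import default_sim_params, generate_cohort


def make_claim(**kw) -> ClaimRecord:
    """A valid claim with overridable fields."""
    base = dict(
        patient_id="P1",
        sex="male",
        age=70,
        insurance="urban_employee",
        hospital_level="tertiary",
        charge_level="tertiary_a",
        los=10,
        cost=1200.0,
        main_dx="I63.9",
        cc_codes=[],
    )
    base.update(kw)
    return ClaimRecord(**base)


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized default synthetic cohort shared across tests."""
    return generate_cohort(default_sim_params(n=4000, seed=11))


@pytest.fixture(scope="session")
def cohort_frame(cohort):
    """The cohort as a strata-augmented frame with fitted patient types."""
    from drgmix.stage1 import CCSeverityClassifier, add_strata_columns
    from drgmix.io import claims_to_frame

    df = add_strata_columns(claims_to_frame(cohort))
    df["patient_type"] = CCSeverityClassifier().fit(df).predict(df)
    return df
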