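"""Phenotype rule engine: per-rule behavior and composition."""

from datetime import date

import pandas as pd
import pytest

from conftest import make_bundle
from nafld_subtypes.phenotype import (
    PhenotypeRuleConfig,
    classify_cohort,
    decide_patient,
    has_liver_disease_code,
    is_excluded,
    persistent_alt_elevation,
)

CFG = PhenotypeRuleConfig()


def _labs(rows):
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "date", "test_name", "value_text", "value_num", "ref_low", "ref_high", "setting"],
    )
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


@pytest.mark.parametrize(
    "rows,sex,expected",
    [
        # valid male pair, 243 days apart -> second date
        (
            [("p", "2014-01-01", "ALT", "", 45, 7, 40, "ambulatory"),
             ("p", "2014-09-01", "ALT", "", 50, 7, 40, "ambulatory")],
            "M",
            (True, date(2014, 9, 1)),
        ),
        # 90-day gap fails the > 6 months requirement
        (
            [("p", "2014-01-01", "ALT", "", 45, 7, 40, "ambulatory"),
             ("p", "2014-04-01", "ALT", "", 50, 7, 40, "ambulatory")],
            "M",
            (False, None),
        ),
        # female threshold 31 applies
        (
            [("p", "2014-01-01", "ALT", "", 35, 7, 40, "ambulatory"),
             ("p", "2015-02-05", "ALT", "", 33, 7, 40, "ambulatory")],
            "F",
            (True, date(2015, 2, 5)),
        ),
        # same values fail for a male patient
        (
            [("p", "2014-01-01", "ALT", "", 35, 7, 40, "ambulatory"),
             ("p", "2015-02-05", "ALT", "", 33, 7, 40, "ambulatory")],
            "M",
            (False, None),
        ),
        # a single extreme value is not persistent elevation
        ([("p", "2014-01-01", "ALT", "", 300, 7, 40, "ambulatory")], "M", (False, None)),
        # inpatient results do not count
        (
            [("p", "2014-01-01", "ALT", "", 45, 7, 40, "inpatient"),
             ("p", "2014-09-01", "ALT", "", 50, 7, 40, "ambulatory")],
            "M",
            (False, None),
        ),
        # exactly 183 days is not "more than 6 months"
        (
            [("p", "2014-01-01", "ALT", "", 45, 7, 40, "ambulatory"),
             ("p", "2014-07-03", "ALT", "", 50, 7, 40, "ambulatory")],
            "M",
            (False, None),
        ),
    ],
)
def test_persistent_alt_rule(rows, sex, expected):
    assert persistent_alt_elevation(_labs(rows), sex, CFG) == expected


def test_unknown_sex_uses_male_threshold():
    rows = [("p", "2014-01-01", "ALT", "", 35, 7, 40, "ambulatory"),
            ("p", "2015-02-05", "ALT", "", 33, 7, 40, "ambulatory")]
    assert persistent_alt_elevation(_labs(rows), "U", CFG) == (False, None)


def test_inclusion_codes():
    codes = pd.DataFrame(
        [("p", "2016-04-01", "ICD9", "571.8", "ambulatory"),
         ("p", "2015-01-01", "ICD9", "571.2", "ambulatory")],
        columns=["patient_id", "date", "system", "code", "setting"],
    )
    codes["date"] = pd.to_datetime(codes["date"])
    assert has_liver_disease_code(codes, CFG) == (True, date(2016, 4, 1))
    only_alcoholic = codes[codes["code"] == "571.2"]
    assert has_liver_disease_code(only_alcoholic, CFG) == (False, None)
    k769 = codes.assign(system="ICD10", code="K76.9")
    assert has_liver_disease_code(k769, CFG)[0] is True


def test_exclusion_channels():
    empty_codes = pd.DataFrame(columns=["patient_id", "date", "system", "code", "setting"])
    empty_meds = pd.DataFrame(columns=["patient_id", "date", "drug_name"])
    hcv = _labs([("p", "2013-01-01", "HCV RNA", "detected", None, None, None, "ambulatory")])
    excluded, reasons = is_excluded(empty_codes, hcv, empty_meds, CFG)
    assert excluded and "positive HCV RNA" in reasons

    amio = pd.DataFrame([("p", "2015-01-01", "Amiodarone")], columns=empty_meds.columns)
    excluded, reasons = is_excluded(empty_codes, _labs([]), amio, CFG)
    assert excluded and any("miodarone" in r for r in reasons)

    clean = is_excluded(empty_codes, _labs([]), empty_meds, CFG)
    assert clean == (False, [])


def test_rule_branch_fixture(rule_branch_bundle):
    """Six hand-built patients reproduce the hand-derived eligibility
    vector and NAFLD dates exactly."""
    bundle, expected = rule_branch_bundle
    out = classify_cohort(bundle)
    pd.testing.assert_frame_equal(
        out[["patient_id", "eligible", "nafld_date"]], expected, check_dtype=False
    )


def test_nafld_date_is_max_of_criterion_dates(rule_branch_bundle):
    bundle, _ = rule_branch_bundle
    # patient A: ALT satisfied 2014-09-01, steatosis note 2015-06-01
    dec = decide_patient(
        "A",
        "M",
        bundle.code_events[bundle.code_events["patient_id"] == "A"],
        bundle.lab_results[bundle.lab_results["patient_id"] == "A"],
        bundle.med_orders[bundle.med_orders["patient_id"] == "A"],
        bundle.documents[bundle.documents["patient_id"] == "A"],
    )
    assert dec.eligible and dec.nafld_date == date(2015, 6, 1)


def test_window_boundaries():
    """Criteria completed before 2013 or after the window end are ineligible."""
    def build(alt_dates, note_date):
        return make_bundle(
            patients=[("p", "1960-01-01", "M", "White", "Not Hispanic", None)],
            labs=[("p", d, "ALT", "", 50, 7, 40, "ambulatory") for d in alt_dates],
            documents=[("p", note_date, "note", "Biopsy shows steatosis.")],
        )

    early = build(["2011-01-01", "2012-01-01"], "2012-11-30")
    assert not classify_cohort(early)["eligible"].iloc[0]
    late = build(["2018-01-01", "2019-01-01"], "2019-06-01")
    assert not classify_cohort(late)["eligible"].iloc[0]
    inside = build(["2011-01-01", "2012-01-01"], "2013-01-01")
    out = classify_cohort(inside)
    assert out["eligible"].iloc[0]
    assert out["nafld_date"].iloc[0] == pd.Timestamp("2013-01-01")


def test_empty_bundle_and_no_steatosis():
    empty = make_bundle()
    assert classify_cohort(empty).empty
    from nafld_subtypes.synthetic import default_cohort_config, generate_cohort
    from dataclasses import replace

    cfg = default_cohort_config(40, seed=2)
    specs = tuple(replace(s, note_mention_profile=(0.0, 0.6, 0.2, 0.2)) for s in cfg.subtype_specs)
    bundle, _, _ = generate_cohort(replace(cfg, subtype_specs=specs, death_note_prob=0.0))
    out = classify_cohort(bundle)
    assert out["eligible"].sum() == 0


def test_exclusion_monotonicity(rule_branch_bundle):
    """Adding an exclusion event can only remove eligibility."""
    bundle, _ = rule_branch_bundle
    extra = pd.DataFrame(
        [("A", pd.Timestamp("2014-01-01"), "ICD9", "070.32", "ambulatory")],
        columns=bundle.code_events.columns,
    )
    tampered = make_bundle()
    tampered.patients = bundle.patients
    tampered.code_events = pd.concat([bundle.code_events, extra], ignore_index=True)
    tampered.lab_results = bundle.lab_results
    tampered.med_orders = bundle.med_orders
    tampered.documents = bundle.documents
    before = classify_cohort(bundle).set_index("patient_id")["eligible"]
    after = classify_cohort(tampered).set_index("patient_id")["eligible"]
    assert not after["A"]
    assert (after[~before.index.isin(["A"])] == before[~before.index.isin(["A"])]).all()


def test_decision_invariant_to_row_order(rule_branch_bundle):
    bundle, _ = rule_branch_bundle
    shuffled = make_bundle()
    shuffled.patients = bundle.patients
    shuffled.code_events = bundle.code_events.sample(frac=1, random_state=1).reset_index(drop=True)
    shuffled.lab_results = bundle.lab_results.sample(frac=1, random_state=2).reset_index(drop=True)
    shuffled.med_orders = bundle.med_orders.sample(frac=1, random_state=3).reset_index(drop=True)
    shuffled.documents = bundle.documents.sample(frac=1, random_state=4).reset_index(drop=True)
    a = classify_cohort(bundle).set_index("patient_id")
    b = classify_cohort(shuffled).set_index("patient_id")
    pd.testing.assert_frame_equal(a, b)
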