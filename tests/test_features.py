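"""Featurization rules: bins, mappings, persistence and abnormality logic."""

import numpy as np
import pandas as pd
import pytest

from nafld_subtypes.features import (
    FeatureMatrix,
    MappingTables,
    age_bin_features,
    assemble_matrix,
    cpt_group_features,
    lab_abnormal_features,
    medication_features,
    phecode_features,
    vital_abnormal_features,
)

MAP = MappingTables.default()


@pytest.mark.parametrize("age,expected", [(53, "age_51_60"), (20, "age_18_20"), (105, "age_101_plus")])
def test_age_bins(age, expected):
    out = age_bin_features(pd.Series([age], index=["p"]))
    assert out.loc["p"].sum() == 1
    assert out.loc["p", expected] == 1


def test_age_below_18_rejected():
    with pytest.raises(ValueError, match="18"):
        age_bin_features(pd.Series([17], index=["p"]))


def _codes(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "system", "code", "setting"])
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def test_phecode_mapping_dedup_and_prevalence():
    ids = [f"p{i}" for i in range(10)]
    rows = [
        ("p0", "2015-01-01", "ICD9", "278.00", "ambulatory"),
        ("p0", "2015-02-01", "ICD10", "E66.9", "ambulatory"),  # same phecode
        ("p1", "2015-01-01", "ICD9", "999.99", "ambulatory"),  # unmapped
    ]
    frame, prov = phecode_features(_codes(rows), ids, MAP, min_prevalence=0.001)
    assert list(frame.columns) == ["phecode_278.1"]
    assert frame.loc["p0", "phecode_278.1"] == 1  # single 1, not 2
    assert frame["phecode_278.1"].sum() == 1
    # prevalence filter: 1/10 >= 0.001 kept; a stricter filter drops it
    strict, _ = phecode_features(_codes(rows), ids, MAP, min_prevalence=0.5)
    assert strict.shape[1] == 0


@pytest.mark.parametrize(
    "code,group,member",
    [("35001", "cpt_cardiovascular_surgery", True), ("33009", "cpt_cardiovascular_surgery", False)],
)
def test_cpt_range_lookup(code, group, member):
    rows = [("p0", "2015-01-01", "CPT", code, "inpatient")]
    frame, _ = cpt_group_features(_codes(rows), ["p0", "p1"], MAP)
    if member:
        assert frame.loc["p0", group] == 1
    else:
        assert group not in frame.columns or frame.loc["p0", group] == 0
    if frame.shape[1]:
        assert frame.loc["p1"].sum() == 0  # no procedures -> all-zero row


def _meds(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "drug_name"])
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def test_medication_persistence_rule():
    ids = ["p0", "p1", "p2"]
    rows = [
        ("p0", "2015-01-01", "metformin"),
        ("p0", "2015-07-20", "metformin"),  # 200 days -> chronic
        ("p1", "2015-01-01", "oxycodone"),
        ("p1", "2015-01-31", "oxycodone"),  # 30 days -> acute, dropped
        ("p2", "2015-01-01", "Glucophage"),
        ("p2", "2015-07-20", "metformin"),  # brands merge to one ingredient
    ]
    frame, _ = medication_features(_meds(rows), ids, MAP)
    assert frame.loc["p0", "med_metformin"] == 1
    assert frame.loc["p2", "med_metformin"] == 1
    assert "med_oxycodone" not in frame.columns


def _labs(rows):
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "date", "test_name", "value_text", "value_num", "ref_low", "ref_high", "setting"],
    )
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def test_lab_abnormality_rules():
    ids = ["p0", "p1", "p2", "p3"]
    rows = [
        ("p0", "2015-01-01", "platelets", "", 120.0, 150, 400, "ambulatory"),  # below low
        ("p1", "2015-01-01", "RPR", "reactive", None, None, None, "ambulatory"),  # term
        ("p2", "2015-01-01", "platelets", "", 150.0, 150, 400, "ambulatory"),  # boundary
        ("p3", "2015-01-01", "platelets", "", 250.0, 150, 400, "ambulatory"),  # normal
    ]
    frame, _ = lab_abnormal_features(_labs(rows), ids, MAP)
    assert frame.loc["p0", "lab_platelets"] == 1
    assert frame.loc["p1", "lab_RPR"] == 1
    assert frame.loc["p2", "lab_platelets"] == 0  # value at bound is normal
    assert frame.loc["p3", "lab_platelets"] == 0


def test_lab_fixture_range_fallback():
    rows = [("p0", "2015-01-01", "ALT", "", 90.0, None, None, "ambulatory")]
    frame, _ = lab_abnormal_features(_labs(rows), ["p0"], MAP)
    assert frame.loc["p0", "lab_ALT"] == 1  # fixture range (7, 40) applies


def _vitals(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "kind", "value", "unit"])
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


@pytest.mark.parametrize(
    "kind,value,unit,column,flag",
    [
        ("temperature", 102.5, "F", "vital_temperature", 1),
        ("temperature", 101.0, "F", "vital_temperature", 0),
        ("temperature", 39.5, "C", "vital_temperature", 1),
        ("sbp", 128.0, "mmHg", "vital_blood_pressure", 0),
        ("dbp", 85.0, "mmHg", "vital_blood_pressure", 1),  # 128/85: DBP > 80
        ("heart_rate", 131.0, "bpm", "vital_heart_rate", 1),
        ("respiratory_rate", 39.0, "bpm", "vital_respiratory_rate", 0),
        ("pain", 8.0, "scale", "vital_pain", 0),
        ("pain", 9.0, "scale", "vital_pain", 1),
    ],
)
def test_vital_thresholds(kind, value, unit, column, flag):
    frame, _ = vital_abnormal_features(
        _vitals([("p0", "2015-01-01", kind, value, unit)]), ["p0"]
    )
    assert frame.loc["p0", column] == flag


def test_assemble_matrix_contracts():
    ids = ["a", "b"]
    b1 = (pd.DataFrame({"f1": [0, 1], "f2": [1, 0]}, index=ids), pd.DataFrame({"feature": ["f1", "f2"], "domain": "x", "concept": ["f1", "f2"]}))
    b2 = (pd.DataFrame({"f3": [1, 1]}, index=ids), pd.DataFrame({"feature": ["f3"], "domain": "y", "concept": ["f3"]}))
    fm = assemble_matrix([b1, b2], ids)
    assert fm.values.shape == (2, 3)
    # permuted patient order realigns rows by id
    fm2 = assemble_matrix(
        [(b1[0].loc[["b", "a"]], b1[1]), (b2[0].loc[["b", "a"]], b2[1])], ids
    )
    assert np.array_equal(fm.values, fm2.values)
    dup = (pd.DataFrame({"f1": [1, 1]}, index=ids), pd.DataFrame({"feature": ["f1"], "domain": "z", "concept": ["f1"]}))
    with pytest.raises(ValueError, match="duplicate"):
        assemble_matrix([b1, dup], ids)


def test_matrix_is_binary_and_idempotent(small_default_world):
    from nafld_subtypes.features import build_feature_matrix
    from nafld_subtypes.phenotype import classify_cohort

    _, bundle, _, _ = small_default_world
    decisions = classify_cohort(bundle)
    m1 = build_feature_matrix(bundle, decisions)
    m2 = build_feature_matrix(bundle, decisions)
    assert np.isin(m1.values, (0, 1)).all()
    # prevalence-filtered domains respect the 0.1% floor (structural
    # blocks like age bins may legitimately be all-zero)
    filtered = m1.provenance["domain"].isin(("diagnoses", "medications")).to_numpy()
    assert (m1.values[:, filtered].mean(axis=0) >= 0.001).all()
    assert m1.feature_names == m2.feature_names
    assert np.array_equal(m1.values, m2.values)


def test_hispanic_ethnicity_sets_race_indicator():
    from nafld_subtypes.features import demographic_features

    patients = pd.DataFrame(
        [
            ("a", pd.Timestamp("1960-01-01"), "F", "White", "Hispanic", None),
            ("b", pd.Timestamp("1960-01-01"), "M", "White", "Not Hispanic", None),
        ],
        columns=["patient_id", "birth_date", "sex", "race", "ethnicity", "death_date"],
    )
    ages = pd.Series([55, 55], index=["a", "b"])
    frame, _ = demographic_features(patients, ages)
    assert frame.loc["a", "race_hispanic"] == 1
    assert frame.loc["a", "race_white"] == 1  # recorded race kept as well
    assert frame.loc["b", "race_hispanic"] == 0
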