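import numpy as np
import pandas as pd
import pytest

from nafld_subtypes.synthetic import EmrBundle


def _empty(columns):
    return pd.DataFrame(columns=columns)


EMPTY_TABLES = {
    "patients": ["patient_id", "birth_date", "sex", "race", "ethnicity", "death_date"],
    "code_events": ["patient_id", "date", "system", "code", "setting"],
    "med_orders": ["patient_id", "date", "drug_name"],
    "lab_results": [
        "patient_id",
        "date",
        "test_name",
        "value_text",
        "value_num",
        "ref_low",
        "ref_high",
        "setting",
    ],
    "vitals": ["patient_id", "date", "kind", "value", "unit"],
    "documents": ["patient_id", "date", "doc_type", "text"],
}


def make_bundle(patients=(), codes=(), meds=(), labs=(), vitals=(), documents=()):
    """Hand-built bundle from row tuples; dates as ISO strings."""
    tables = {}
    for name, rows in (
        ("patients", patients),
        ("code_events", codes),
        ("med_orders", meds),
        ("lab_results", labs),
        ("vitals", vitals),
        ("documents", documents),
    ):
        cols = EMPTY_TABLES[name]
        frame = pd.DataFrame(list(rows), columns=cols) if len(rows) else _empty(cols)
        for col in cols:
            if col.endswith("date") or col == "date":
                frame[col] = pd.to_datetime(frame[col])
        tables[name] = frame
    return EmrBundle(**tables)


@pytest.fixture(scope="session")
def rule_branch_bundle():
    """Six patients covering each phenotype rule branch.

    A: valid male ALT pair + positive note          -> eligible 2015-06-01
    B: male ALT pair only 90 days apart             -> ineligible
    C: female pair at the 31 IU/mL threshold, 400 d -> eligible 2015-02-05
    D: inclusion code but HCV RNA detected          -> ineligible (excluded)
    E: inclusion code but steatogenic medication    -> ineligible (excluded)
    F: valid ALT pair but only negated steatosis    -> ineligible
    """
    patients = [
        ("A", "1960-01-01", "M", "White", "Not Hispanic", None),
        ("B", "1960-01-01", "M", "White", "Not Hispanic", None),
        ("C", "1965-05-05", "F", "Black", "Hispanic", None),
        ("D", "1950-03-03", "M", "Asian", "Not Hispanic", None),
        ("E", "1955-07-07", "F", "White", "Not Hispanic", None),
        ("F", "1962-09-09", "M", "Other", "Not Hispanic", None),
    ]
    labs = [
        ("A", "2014-01-01", "ALT", "", 45.0, 7, 40, "ambulatory"),
        ("A", "2014-09-01", "ALT", "", 50.0, 7, 40, "ambulatory"),
        ("B", "2014-01-01", "ALT", "", 45.0, 7, 40, "ambulatory"),
        ("B", "2014-04-01", "ALT", "", 50.0, 7, 40, "ambulatory"),
        ("C", "2014-01-01", "ALT", "", 35.0, 7, 40, "ambulatory"),
        ("C", "2015-02-05", "ALT", "", 33.0, 7, 40, "ambulatory"),
        ("D", "2013-01-01", "HCV RNA", "detected", None, None, None, "ambulatory"),
        ("F", "2014-02-01", "ALT", "", 60.0, 7, 40, "ambulatory"),
        ("F", "2015-02-01", "ALT", "", 70.0, 7, 40, "ambulatory"),
    ]
    codes = [
        ("D", "2016-04-01", "ICD10", "K76.0", "ambulatory"),
        ("E", "2016-04-01", "ICD9", "571.8", "ambulatory"),
    ]
    meds = [("E", "2015-01-01", "amiodarone")]
    documents = [
        ("A", "2015-06-01", "note", "Liver biopsy shows hepatic steatosis."),
        ("B", "2014-05-01", "imaging", "Findings are consistent with fatty liver."),
        ("C", "2014-06-01", "imaging", "Ultrasound reveals moderate steatosis."),
        ("D", "2016-05-01", "note", "Imaging demonstrates steatosis of the liver."),
        ("E", "2016-03-01", "note", "Findings are consistent with steatohepatitis."),
        ("F", "2015-03-01", "imaging", "There is absence of steatosis."),
    ]
    expected = pd.DataFrame(
        {
            "patient_id": list("ABCDEF"),
            "eligible": [True, False, True, False, False, False],
            "nafld_date": pd.to_datetime(
                ["2015-06-01", None, "2015-02-05", None, None, None]
            ),
        }
    )
    return make_bundle(patients, codes, meds, labs, (), documents), expected


@pytest.fixture(scope="session")
def small_default_world():
    """One modest default-world cohort shared across tests."""
    from nafld_subtypes.synthetic import default_cohort_config, generate_cohort

    config = default_cohort_config(250, seed=20240915)
    bundle, truth, doc_truth = generate_cohort(config)
    return config, bundle, truth, doc_truth


@pytest.fixture(scope="session")
def toy_matrix():
    """Tiny 40-patient binary matrix with one subtype-specific feature."""
    from nafld_subtypes.features import FeatureMatrix

    rng = np.random.default_rng(7)
    values = rng.integers(0, 2, size=(40, 6)).astype(np.uint8)
    labels = np.repeat([1, 2], 20)
    values[:, 0] = (labels == 2).astype(np.uint8)  # only present in subtype 2
    names = [f"f{i}" for i in range(6)]
    return FeatureMatrix(
        patient_ids=[f"P{i}" for i in range(40)], feature_names=names, values=values
    ), labels
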