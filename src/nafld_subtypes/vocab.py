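"""Shared vocabulary fixtures: code maps, drug ingredients, lab ranges.

The real analysis would use full ICD->phecode, CPT, and RxNorm
vocabularies; this package abstracts them to small editable CSV fixtures
shipped under ``data/``.  Both the synthetic generator and the feature
builders read from the same files so that generated events are always
mappable.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

#: dx concept -> (ICD-9 code, ICD-10 code); phecode comes from the map file
DX_CONCEPTS = {
    "obesity": ("278.00", "E66.9"),
    "type2_diabetes": ("250.00", "E11.9"),
    "hypertension": ("401.9", "I10"),
    "hyperlipidemia": ("272.4", "E78.5"),
    "gerd": ("530.81", "K21.9"),
    "asthma": ("493.90", "J45.909"),
    "depression": ("311", "F32.9"),
    "anxiety": ("300.00", "F41.9"),
    "tobacco_use": ("305.1", "F17.210"),
    "osa": ("327.23", "G47.33"),
    "vitamin_d_deficiency": ("268.9", "E55.9"),
    "atrial_fibrillation": ("427.31", "I48.91"),
    "uti": ("599.0", "N39.0"),
    "pneumonia": ("486", "J18.9"),
    "sepsis": ("995.91", "A41.9"),
    "malignancy": ("199.1", "C80.1"),
    "heart_failure": ("428.0", "I50.9"),
    "copd": ("496", "J44.9"),
    "anemia": ("285.9", "D64.9"),
    "hypothyroidism": ("244.9", "E03.9"),
}

NAFLD_INCLUSION_ICD9 = ("571.5", "571.8", "571.9")
NAFLD_INCLUSION_ICD10 = ("K75.81", "K76.0", "K76.9")

#: outcome -> (ICD-9 example code, ICD-10 example code) emitted on events
OUTCOME_EVENT_CODES = {
    "hcc": ("155.0", "C22.0"),
    "ckd": ("585.9", "N18.9"),
    "cvd": ("414.01", "I25.10"),
    "mi": ("410.90", "I21.9"),
}

#: CPT surgery concept -> a representative code inside its group range
CPT_CONCEPT_CODES = {
    "cardiovascular_surgery": "35001",
    "digestive_surgery": "44950",
    "respiratory_surgery": "31622",
}
CPT_DIALYSIS_CODE = "90945"

#: lab concept -> direction of the typical abnormality
LAB_ABNORMAL_DIRECTION = {
    "ALT": "high",
    "AST": "high",
    "platelets": "low",
    "bilirubin_total": "high",
    "albumin": "low",
    "INR": "high",
    "creatinine": "high",
    "hemoglobin": "low",
    "hba1c": "high",
}

VITAL_KINDS = ("temperature", "sbp", "dbp", "heart_rate", "respiratory_rate", "pain")


def _read(name: str) -> pd.DataFrame:
    with resources.files("nafld_subtypes.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=None)
def icd_phecode_map() -> pd.DataFrame:
    return _read("icd_phecode_map.csv")


@lru_cache(maxsize=None)
def cpt_groups() -> pd.DataFrame:
    df = _read("cpt_groups.csv")
    return df.astype({"start": int, "end": int})


@lru_cache(maxsize=None)
def drug_ingredients() -> dict:
    df = _read("drug_ingredients.csv")
    return dict(zip(df["drug_name"], df["ingredient"]))


@lru_cache(maxsize=None)
def lab_reference() -> dict:
    df = _read("lab_reference.csv").astype({"ref_low": float, "ref_high": float})
    return {r.test_name: (r.ref_low, r.ref_high) for r in df.itertuples()}


@lru_cache(maxsize=None)
def exclusion_codes() -> pd.DataFrame:
    return _read("exclusion_codes.csv")


@lru_cache(maxsize=None)
def steatogenic_meds() -> frozenset:
    return frozenset(_read("steatogenic_meds.csv")["drug_name"].str.lower())


@lru_cache(maxsize=None)
def abnormal_terms() -> tuple:
    return tuple(_read("abnormal_terms.csv")["term"])
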