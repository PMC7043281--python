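"""Binary featurization of an eligible cohort's EMR.

Every feature is a 0/1 patient-level indicator:

* demographics — ten age bins at the NAFLD diagnosis date, sex, and
  race/ethnicity categories (Hispanic ethnicity also sets the Hispanic
  race indicator);
* diagnoses — ICD events mapped to phecodes, kept at >= 0.1% cohort
  prevalence;
* procedures — CPT codes mapped to their second-level group by range
  lookup;
* medications — drug names mapped to ingredient concepts, flagged only
  when two orders are >= 183 days apart (chronic use), prevalence-filtered;
* labs — one column per test, 1 when any result is qualitatively
  abnormal (term match) or numerically outside the reference range
  (strict inequalities: a value equal to a bound is normal);
* vitals — five fixed columns (temperature > 39 C / 102 F, SBP > 130 or
  DBP > 80, heart rate > 130, respiratory rate > 40, pain 9-10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab
from .synthetic import EmrBundle

log = logging.getLogger(__name__)

AGE_BINS = (
    (18, 20),
    (21, 30),
    (31, 40),
    (41, 50),
    (51, 60),
    (61, 70),
    (71, 80),
    (81, 90),
    (91, 100),
    (101, None),
)
RACE_CATEGORIES = (
    "Asian",
    "Black",
    "Indian/Native",
    "Pacific Islander",
    "White",
    "Hispanic",
    "Other",
    "Unknown",
)


@dataclass(frozen=True)
class MappingTables:
    """User-editable vocabularies backing the featurizer."""

    icd_to_phecode: dict  # (system, code) -> phecode
    cpt_groups: tuple  # ((start, end, label), ...) sorted, non-overlapping
    drug_to_ingredient: dict  # lowercased drug name -> ingredient
    lab_reference: dict  # test name -> (low, high)
    abnormal_terms: tuple = ()

    def __post_init__(self):
        ranges = sorted(self.cpt_groups)
        for (s1, e1, _), (s2, _, _) in zip(ranges, ranges[1:]):
            if e1 >= s2:
                raise ValueError("CPT group ranges overlap")
        for s, e, _ in ranges:
            if s > e:
                raise ValueError(f"CPT range start {s} > end {e}")

    @classmethod
    def default(cls) -> "MappingTables":
        pm = vocab.icd_phecode_map()
        cg = vocab.cpt_groups()
        return cls(
            icd_to_phecode=dict(zip(zip(pm["system"], pm["code"]), pm["phecode"])),
            cpt_groups=tuple(cg[["start", "end", "group"]].itertuples(index=False, name=None)),
            drug_to_ingredient={k.lower(): v for k, v in vocab.drug_ingredients().items()},
            lab_reference=vocab.lab_reference(),
            abnormal_terms=vocab.abnormal_terms(),
        )


@dataclass
class FeatureMatrix:
    """Patients x binary features with per-column provenance."""

    patient_ids: list
    feature_names: list
    values: np.ndarray  # (n_patients, n_features) uint8
    provenance: pd.DataFrame = None  # columns: feature, domain, concept

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("matrix shape inconsistent with ids/names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = {f for f in self.feature_names if self.feature_names.count(f) > 1}
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.feature_names)


def _block(frame: pd.DataFrame, domain: str) -> tuple:
    prov = pd.DataFrame(
        {"feature": frame.columns, "domain": domain, "concept": frame.columns}
    )
    return frame, prov


def age_bin_features(ages: pd.Series) -> pd.DataFrame:
    """One-hot age bins; exactly one indicator per patient.

    Ages below 18 are a validation error (the cohort is adult by
    construction).
    """
    if (ages < 18).any():
        bad = ages[ages < 18]
        raise ValueError(f"ages below 18 are outside the cohort definition: {bad.to_dict()}")
    cols = {}
    for lo, hi in AGE_BINS:
        name = f"age_{lo}_plus" if hi is None else f"age_{lo}_{hi}"
        if hi is None:
            cols[name] = (ages >= lo).astype(np.uint8)
        else:
            cols[name] = ((ages >= lo) & (ages <= hi)).astype(np.uint8)
    out = pd.DataFrame(cols, index=ages.index)
    # integer truncation of age makes the bins exhaustive and exclusive
    assert (out.sum(axis=1) == 1).all()
    return out


def demographic_features(patients: pd.DataFrame, ages: pd.Series) -> tuple:
    """Age bins + sex + race/ethnicity indicators."""
    pts = patients.set_index("patient_id")
    age_block = age_bin_features(ages)
    demo = pd.DataFrame(index=age_block.index)
    demo["sex_female"] = (pts.loc[age_block.index, "sex"] == "F").astype(np.uint8)
    race = pts.loc[age_block.index, "race"].where(
        pts.loc[age_block.index, "race"].isin(RACE_CATEGORIES), "Other"
    )
    hispanic = pts.loc[age_block.index, "ethnicity"] == "Hispanic"
    for cat in RACE_CATEGORIES:
        col = (race == cat).astype(np.uint8)
        if cat == "Hispanic":
            col = (col.astype(bool) | hispanic).astype(np.uint8)
        demo[f"race_{cat.lower().replace('/', '_').replace(' ', '_')}"] = col
    demo["ethnicity_hispanic"] = hispanic.astype(np.uint8)
    frame = pd.concat([age_block, demo], axis=1)
    return _block(frame, "demographics")


def phecode_features(
    code_events: pd.DataFrame,
    patient_ids: list,
    mapping: MappingTables,
    min_prevalence: float = 0.001,
) -> tuple:
    """ICD events -> phecode indicators, prevalence-filtered (mean >= 0.001)."""
    frame = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    icd = code_events[code_events["system"].isin(("ICD9", "ICD10"))]
    icd = icd[icd["patient_id"].isin(frame.index)]
    mapped = {}
    unmapped = set()
    for row in icd.itertuples():
        phe = mapping.icd_to_phecode.get((row.system, row.code))
        if phe is None:
            unmapped.add((row.system, row.code))
            continue
        mapped.setdefault(f"phecode_{phe}", set()).add(row.patient_id)
    if unmapped:
        log.info("phecode mapping: %d unmapped codes %s", len(unmapped), sorted(unmapped)[:10])
    for name in sorted(mapped):
        frame[name] = frame.index.isin(mapped[name]).astype(np.uint8)
    keep = [c for c in frame.columns if frame[c].mean() >= min_prevalence]
    return _block(frame[keep], "diagnoses")


def cpt_group_features(
    code_events: pd.DataFrame, patient_ids: list, mapping: MappingTables
) -> tuple:
    """CPT events -> second-level group indicators via range lookup."""
    frame = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    cpt = code_events[code_events["system"] == "CPT"]
    cpt = cpt[cpt["patient_id"].isin(frame.index)]
    groups = {}
    for row in cpt.itertuples():
        try:
            code = int(str(row.code))
        except ValueError:
            log.info("non-numeric CPT code %r ungrouped", row.code)
            continue
        for start, end, label in mapping.cpt_groups:
            if start <= code <= end:
                groups.setdefault(f"cpt_{label}", set()).add(row.patient_id)
                break
        else:
            log.info("CPT code %s outside all group ranges (ungrouped)", code)
    for name in sorted(groups):
        frame[name] = frame.index.isin(groups[name]).astype(np.uint8)
    return _block(frame, "procedures")


def medication_features(
    med_orders: pd.DataFrame,
    patient_ids: list,
    mapping: MappingTables,
    min_prevalence: float = 0.001,
    min_gap_days: int = 183,
) -> tuple:
    """Ingredient indicators for chronic use: two orders >= min_gap_days apart."""
    frame = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    meds = med_orders[med_orders["patient_id"].isin(frame.index)].copy()
    if not meds.empty:
        meds["ingredient"] = meds["drug_name"].str.lower().map(mapping.drug_to_ingredient)
        n_unmapped = meds["ingredient"].isna().sum()
        if n_unmapped:
            log.info("medication mapping: %d unmapped orders", n_unmapped)
        meds = meds.dropna(subset=["ingredient"])
        span = meds.groupby(["patient_id", "ingredient"])["date"].agg(["min", "max"])
        chronic = span[(span["max"] - span["min"]).dt.days >= min_gap_days]
        for ingredient, sub in chronic.reset_index().groupby("ingredient"):
            frame[f"med_{ingredient}"] = frame.index.isin(sub["patient_id"]).astype(np.uint8)
    frame = frame[sorted(frame.columns)]
    keep = [c for c in frame.columns if frame[c].mean() >= min_prevalence]
    return _block(frame[keep], "medications")


def _is_abnormal_text(text: str, terms: tuple) -> bool:
    folded = str(text).strip().lower()
    return bool(folded) and any(t in folded for t in terms)


def lab_abnormal_features(
    lab_results: pd.DataFrame, patient_ids: list, mapping: MappingTables
) -> tuple:
    """Per-test abnormality indicators.

    A result is abnormal when its free text matches an abnormal term or
    its numeric value lies strictly outside the reference range (row
    range first, fixture fallback).  Numeric tests with no range anywhere
    are omitted and logged.
    """
    frame = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    labs = lab_results[lab_results["patient_id"].isin(frame.index)]
    terms = tuple(t.lower() for t in (mapping.abnormal_terms or vocab.abnormal_terms()))
    abnormal: dict = {}
    skipped_tests = set()
    for row in labs.itertuples():
        test = row.test_name
        hit = False
        if _is_abnormal_text(row.value_text, terms):
            hit = True
        elif row.value_num is not None and not pd.isna(row.value_num):
            lo, hi = row.ref_low, row.ref_high
            if pd.isna(lo) or pd.isna(hi):
                lo, hi = mapping.lab_reference.get(test, (None, None))
            if lo is None or hi is None or pd.isna(lo) or pd.isna(hi):
                skipped_tests.add(test)
                continue
            hit = row.value_num < lo or row.value_num > hi
        if hit:
            abnormal.setdefault(f"lab_{test}", set()).add(row.patient_id)
    if skipped_tests:
        log.info("labs without any reference range omitted: %s", sorted(skipped_tests))
    for name in sorted(abnormal):
        frame[name] = frame.index.isin(abnormal[name]).astype(np.uint8)
    return _block(frame, "labs")


def vital_abnormal_features(vitals: pd.DataFrame, patient_ids: list) -> tuple:
    """Five fixed abnormal-vital indicators (single occurrence suffices)."""
    frame = pd.DataFrame(
        0,
        index=pd.Index(patient_ids, name="patient_id"),
        columns=[
            "vital_temperature",
            "vital_blood_pressure",
            "vital_heart_rate",
            "vital_respiratory_rate",
            "vital_pain",
        ],
        dtype=np.uint8,
    )
    vit = vitals[vitals["patient_id"].isin(frame.index)]
    for row in vit.itertuples():
        kind, value, unit = row.kind, row.value, str(row.unit)
        pid = row.patient_id
        if kind == "temperature":
            if unit.upper().startswith("F"):
                hit = value > 102.0
            elif unit.upper().startswith("C"):
                hit = value > 39.0
            else:
                log.info("temperature with unknown unit %r skipped", unit)
                continue
            if hit:
                frame.loc[pid, "vital_temperature"] = 1
        elif kind == "sbp" and value > 130:
            frame.loc[pid, "vital_blood_pressure"] = 1
        elif kind == "dbp" and value > 80:
            frame.loc[pid, "vital_blood_pressure"] = 1
        elif kind == "heart_rate" and value > 130:
            frame.loc[pid, "vital_heart_rate"] = 1
        elif kind == "respiratory_rate" and value > 40:
            frame.loc[pid, "vital_respiratory_rate"] = 1
        elif kind == "pain" and value >= 9:
            frame.loc[pid, "vital_pain"] = 1
    return _block(frame, "vitals")


def assemble_matrix(blocks: list, patient_ids: list) -> FeatureMatrix:
    """Column-concatenate feature blocks into one FeatureMatrix.

    Blocks are (frame, provenance) pairs; rows are aligned on patient id,
    and the column order is deterministic (block order as given, column
    order within each block as produced).
    """
    idx = pd.Index(patient_ids, name="patient_id")
    frames, provs = [], []
    for frame, prov in blocks:
        if len(frame) != len(idx):
            raise ValueError("feature block row count does not match patient list")
        frames.append(frame.reindex(idx))
        provs.append(prov)
    joined = pd.concat(frames, axis=1)
    if joined.isna().any().any():
        raise ValueError("feature blocks missing rows for some patients")
    provenance = pd.concat(provs, ignore_index=True)
    return FeatureMatrix(
        patient_ids=list(idx),
        feature_names=list(joined.columns),
        values=joined.to_numpy(dtype=np.uint8),
        provenance=provenance,
    )


def build_feature_matrix(
    bundle: EmrBundle,
    decisions: pd.DataFrame,
    mapping: MappingTables | None = None,
    min_prevalence: float = 0.001,
) -> FeatureMatrix:
    """Featurize the eligible cohort of a bundle end to end."""
    mapping = mapping or MappingTables.default()
    elig = decisions[decisions["eligible"]].copy()
    patient_ids = list(elig["patient_id"])
    if not patient_ids:
        raise ValueError("no eligible patients to featurize")
    pts = bundle.patients.set_index("patient_id").loc[patient_ids]
    nafld = elig.set_index("patient_id")["nafld_date"]
    ages = pd.Series(
        ((pd.to_datetime(nafld) - pd.to_datetime(pts["birth_date"])).dt.days // 365.25).astype(int),
        index=pts.index,
    )
    blocks = [
        demographic_features(bundle.patients, ages),
        phecode_features(bundle.code_events, patient_ids, mapping, min_prevalence),
        cpt_group_features(bundle.code_events, patient_ids, mapping),
        medication_features(bundle.med_orders, patient_ids, mapping, min_prevalence),
        lab_abnormal_features(bundle.lab_results, patient_ids, mapping),
        vital_abnormal_features(bundle.vitals, patient_ids),
    ]
    return assemble_matrix(blocks, patient_ids)
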