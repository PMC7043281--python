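"""Rule-based electronic phenotype for NAFLD.

A patient enters the cohort when all of the following hold:

1. *Liver-disease signal*: persistent ALT elevation (two or more
   ambulatory ALT results at/above the sex-specific threshold, more than
   six months apart) OR a chronic non-specific / non-alcoholic liver
   disease diagnosis code.
2. *No exclusion*: no viral hepatitis, alcoholic liver disease, or other
   chronic liver disease code at any time; no positive HBsAg or
   detectable HCV RNA lab; no steatogenic medication order.
3. *Steatosis evidence*: a positive (non-negated, non-family) mention of
   hepatic steatosis or a synonym in any imaging, pathology, or note
   document.

The NAFLD diagnosis date is the earliest date on which the patient meets
all required criteria simultaneously, i.e. the latest of the earliest
satisfaction dates of criteria 1 and 3; it must fall after 2012-12-31 and
no later than 2019-01-31, otherwise the patient is ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from . import vocab
from .synthetic import EmrBundle
from .textmining import STEATOSIS_LEXICON, find_mentions


@dataclass(frozen=True)
class PhenotypeRuleConfig:
    alt_threshold_male: float = 40.0  # IU/mL
    alt_threshold_female: float = 31.0
    min_gap_days: int = 183  # "more than 6 months" = strictly > 183 days
    inclusion_icd9: tuple = vocab.NAFLD_INCLUSION_ICD9
    inclusion_icd10: tuple = vocab.NAFLD_INCLUSION_ICD10
    window_start_exclusive: date = date(2012, 12, 31)
    window_end_inclusive: date = date(2019, 1, 31)
    require_both_channels: bool = False  # AND instead of OR for ALT/ICD
    exclusion_codes: frozenset = None  # {(system, code)}; default from fixture
    steatogenic_meds: frozenset = None  # lowercased drug names
    positive_qual_terms: tuple = ("positive", "reactive", "detected")

    def resolved_exclusions(self) -> frozenset:
        if self.exclusion_codes is not None:
            return self.exclusion_codes
        df = vocab.exclusion_codes()
        return frozenset(zip(df["system"], df["code"]))

    def resolved_steatogenic(self) -> frozenset:
        if self.steatogenic_meds is not None:
            return self.steatogenic_meds
        return vocab.steatogenic_meds()


@dataclass
class PhenotypeDecision:
    patient_id: str
    eligible: bool
    nafld_date: date | None
    criteria_trace: dict = field(default_factory=dict)

    @property
    def failed_rules(self) -> list:
        return [k for k, v in self.criteria_trace.items() if not v.get("passed", True)]


def _as_date(value) -> date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    return value


def persistent_alt_elevation(labs: pd.DataFrame, sex: str, config: PhenotypeRuleConfig) -> tuple:
    """(rule met?, qualifying date) for the persistent-ALT criterion.

    The qualifying date is the second (later) date of the earliest pair of
    ambulatory ALT results at/above the sex threshold more than
    ``min_gap_days`` apart.  Unknown sex falls back to the (stricter) male
    threshold.
    """
    threshold = {
        "M": config.alt_threshold_male,
        "F": config.alt_threshold_female,
    }.get(sex, config.alt_threshold_male)
    if labs.empty:
        return False, None
    alt = labs[
        (labs["test_name"] == "ALT")
        & (labs["setting"] == "ambulatory")
        & (labs["value_num"].notna())
        & (labs["value_num"] >= threshold)
    ]
    if len(alt) < 2:
        return False, None
    dates = sorted(_as_date(d) for d in alt["date"])
    first = dates[0]
    for d in dates[1:]:
        if (d - first).days > config.min_gap_days:
            return True, d
    return False, None


def has_liver_disease_code(code_events: pd.DataFrame, config: PhenotypeRuleConfig) -> tuple:
    """(code present?, earliest matching date) for the inclusion ICD sets."""
    if code_events.empty:
        return False, None
    inc9, inc10 = set(config.inclusion_icd9), set(config.inclusion_icd10)
    hits = code_events[
        ((code_events["system"] == "ICD9") & (code_events["code"].isin(inc9)))
        | ((code_events["system"] == "ICD10") & (code_events["code"].isin(inc10)))
    ]
    if hits.empty:
        return False, None
    return True, _as_date(hits["date"].min())


def is_excluded(
    code_events: pd.DataFrame,
    labs: pd.DataFrame,
    meds: pd.DataFrame,
    config: PhenotypeRuleConfig,
) -> tuple:
    """(excluded?, list of reasons) over the patient's entire record."""
    reasons = []
    exclusions = config.resolved_exclusions()
    if not exclusions:
        raise ValueError("exclusion code set is empty; supply exclusion lists")
    if not code_events.empty:
        for row in code_events.itertuples():
            if (row.system, row.code) in exclusions:
                reasons.append(f"exclusion code {row.system}:{row.code}")
    if not labs.empty:
        viral = labs[labs["test_name"].isin(("HBsAg", "HCV RNA"))]
        for row in viral.itertuples():
            text = str(row.value_text).strip().lower()
            if any(term in text for term in config.positive_qual_terms):
                reasons.append(f"positive {row.test_name}")
    steatogenic = config.resolved_steatogenic()
    if not meds.empty:
        for name in meds["drug_name"]:
            if str(name).lower() in steatogenic:
                reasons.append(f"steatogenic medication {name}")
    return bool(reasons), sorted(set(reasons))


def steatosis_evidence(documents: pd.DataFrame) -> tuple:
    """(positive mention present?, earliest positive-mention date)."""
    earliest = None
    if not documents.empty:
        for row in documents.itertuples():
            for m in find_mentions(row.text, STEATOSIS_LEXICON):
                if m.polarity == "positive":
                    d = _as_date(row.date)
                    if earliest is None or d < earliest:
                        earliest = d
    return earliest is not None, earliest


def decide_patient(
    patient_id: str,
    sex: str,
    code_events: pd.DataFrame,
    labs: pd.DataFrame,
    meds: pd.DataFrame,
    documents: pd.DataFrame,
    config: PhenotypeRuleConfig | None = None,
) -> PhenotypeDecision:
    """Evaluate every phenotype rule for one patient and compose them."""
    config = config or PhenotypeRuleConfig()
    trace = {}

    alt_ok, alt_date = persistent_alt_elevation(labs, sex, config)
    trace["persistent_alt"] = {"passed": alt_ok, "date": alt_date}
    if sex not in ("M", "F"):
        trace["persistent_alt"]["note"] = "unknown sex; male threshold applied"

    icd_ok, icd_date = has_liver_disease_code(code_events, config)
    trace["inclusion_icd"] = {"passed": icd_ok, "date": icd_date}

    if config.require_both_channels:
        liver_ok = alt_ok and icd_ok
        liver_date = max(d for d in (alt_date, icd_date) if d is not None) if liver_ok else None
    else:
        liver_ok = alt_ok or icd_ok
        candidates = [d for d in (alt_date, icd_date) if d is not None]
        liver_date = min(candidates) if candidates else None
    trace["liver_disease_signal"] = {"passed": liver_ok, "date": liver_date}

    excluded, reasons = is_excluded(code_events, labs, meds, config)
    trace["no_exclusion"] = {"passed": not excluded, "reasons": reasons}

    stea_ok, stea_date = steatosis_evidence(documents)
    trace["steatosis_evidence"] = {"passed": stea_ok, "date": stea_date}

    eligible = liver_ok and not excluded and stea_ok
    nafld_date = None
    if eligible:
        nafld_date = max(liver_date, stea_date)
        in_window = (
            nafld_date > config.window_start_exclusive
            and nafld_date <= config.window_end_inclusive
        )
        trace["index_window"] = {"passed": in_window, "date": nafld_date}
        if not in_window:
            eligible, nafld_date = False, None
    return PhenotypeDecision(
        patient_id=patient_id, eligible=eligible, nafld_date=nafld_date, criteria_trace=trace
    )


def classify_cohort(bundle: EmrBundle, config: PhenotypeRuleConfig | None = None) -> pd.DataFrame:
    """Apply the phenotype to every patient in a bundle.

    Returns one row per patient: patient_id, eligible, nafld_date,
    failed_rules (semicolon-joined rule names).
    """
    config = config or PhenotypeRuleConfig()
    by_patient = {
        name: dict(iter(tbl.groupby("patient_id", sort=False)))
        for name, tbl in bundle.tables().items()
        if name != "patients"
    }
    empty = {name: tbl.iloc[0:0] for name, tbl in bundle.tables().items()}
    rows = []
    for p in bundle.patients.itertuples():
        decision = decide_patient(
            p.patient_id,
            p.sex,
            by_patient["code_events"].get(p.patient_id, empty["code_events"]),
            by_patient["lab_results"].get(p.patient_id, empty["lab_results"]),
            by_patient["med_orders"].get(p.patient_id, empty["med_orders"]),
            by_patient["documents"].get(p.patient_id, empty["documents"]),
            config,
        )
        rows.append(
            {
                "patient_id": decision.patient_id,
                "eligible": decision.eligible,
                "nafld_date": pd.Timestamp(decision.nafld_date) if decision.nafld_date else pd.NaT,
                "failed_rules": ";".join(decision.failed_rules),
            }
        )
    out = pd.DataFrame(
        rows, columns=["patient_id", "eligible", "nafld_date", "failed_rules"]
    )
    return out
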