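"""Synthetic multi-table EMR generator with a planted subtype structure.

No EMR extract accompanies the analysis this package reproduces, so every
downstream stage is exercised on synthetic bundles: per-patient tables of
demographics, coded events, medication orders, labs, vitals, and free-text
documents, generated from a latent subtype assignment.  Each subtype is a
:class:`SubtypeSpec`: a mixing proportion, Bernoulli prevalences for
diagnosis / medication / lab / procedure / vital concepts, constant
(exponential) hazards for the six study outcomes, and a distribution over
how the steatosis evidence appears in note text (positive, negated,
family-history, or absent mention).

The generator's defaults state a world loosely shaped like the published
cohort narrative (five subtypes, two of them covering ~87% of patients,
the small ones sicker with much higher death hazards); it makes no claim
of matching the real cohort's correlation structure.  The hidden truth
(subtype labels and latent event times) is returned separately and never
leaks into the bundle tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import vocab

OUTCOMES = ("death", "cirrhosis", "hcc", "ckd", "cvd", "mi")
MENTION_KINDS = ("positive", "negated", "family", "absent")

DEFAULT_WINDOW = (date(2013, 1, 1), date(2019, 1, 31))

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SubtypeSpec:
    """Latent description of one planted subtype."""

    label: int
    mixing_proportion: float
    feature_prevalences: dict  # concept ("dx:...", "med:...", ...) -> prob
    outcome_hazards: dict  # outcome -> events per person-year
    note_mention_profile: tuple = (0.88, 0.05, 0.03, 0.04)  # pos/neg/fam/absent
    age_mean: float = 53.0
    age_sd: float = 14.0
    female_prob: float = 0.5
    hispanic_prob: float = 0.17
    race_probs: dict = field(
        default_factory=lambda: {
            "White": 0.50,
            "Black": 0.12,
            "Asian": 0.07,
            "Other": 0.16,
            "Unknown": 0.15,
        }
    )
    meld_mean: float = 9.0
    meld_sd: float = 3.0

    def validate(self) -> None:
        if not 0.0 <= self.mixing_proportion <= 1.0:
            raise ValueError(f"subtype {self.label}: mixing proportion outside [0,1]")
        for concept, p in self.feature_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"subtype {self.label}: prevalence {p} for {concept} outside [0,1]")
        for outcome, h in self.outcome_hazards.items():
            if h < 0:
                raise ValueError(f"subtype {self.label}: negative hazard for {outcome}")
        if abs(sum(self.note_mention_profile) - 1.0) > 1e-9 or any(
            p < 0 for p in self.note_mention_profile
        ):
            raise ValueError(f"subtype {self.label}: note mention profile is not a distribution")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    seed: int
    index_window: tuple = DEFAULT_WINDOW
    subtype_specs: tuple = ()
    alt_rule_prob: float = 0.8  # qualify via the persistent-ALT route
    icd_rule_prob: float = 0.5  # qualify via an inclusion ICD code
    exclusion_prob: float = 0.03  # carry a disqualifying code/lab/med
    death_note_prob: float = 0.6
    meld_note_prob: float = 0.4

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.index_window[0] >= self.index_window[1]:
            raise ValueError("index window start must precede end")
        if not self.subtype_specs:
            raise ValueError("at least one subtype spec is required")
        total = sum(s.mixing_proportion for s in self.subtype_specs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing proportions sum to {total}, expected 1")
        for p in (self.alt_rule_prob, self.icd_rule_prob, self.exclusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("generator probabilities must lie in [0,1]")
        for spec in self.subtype_specs:
            spec.validate()


@dataclass
class EmrBundle:
    """The set of per-patient tables the pipeline consumes."""

    patients: pd.DataFrame
    code_events: pd.DataFrame
    med_orders: pd.DataFrame
    lab_results: pd.DataFrame
    vitals: pd.DataFrame
    documents: pd.DataFrame

    def tables(self) -> dict:
        return {
            "patients": self.patients,
            "code_events": self.code_events,
            "med_orders": self.med_orders,
            "lab_results": self.lab_results,
            "vitals": self.vitals,
            "documents": self.documents,
        }


# ---------------------------------------------------------------------------
# note templates

_POSITIVE_TEMPLATES = (
    "Liver biopsy shows {term}.",
    "Imaging demonstrates {term} of the liver.",
    "Findings are consistent with {term}.",
    "Ultrasound reveals moderate {term}.",
)
_NEGATED_TEMPLATES = (
    "There is absence of {term}.",
    "No evidence of {term} on imaging.",
    "Negative for {term}.",
    "Biopsy without {term}.",
)
_FAMILY_TEMPLATES = (
    "Mother with {term}.",
    "Family history of {term}.",
    "Patient's brother has {term}.",
)
_ABSENT_TEMPLATES = (
    "Routine follow-up visit, no acute complaints.",
    "Medication list reviewed and reconciled.",
    "Patient counseled on diet and exercise.",
)
_TEMPLATES = {
    "positive": _POSITIVE_TEMPLATES,
    "negated": _NEGATED_TEMPLATES,
    "family": _FAMILY_TEMPLATES,
    "absent": _ABSENT_TEMPLATES,
}


def generate_note_text(mention_kind: str, term: str, rng: np.random.Generator) -> str:
    """A templated sentence embedding ``term`` per the mention kind.

    ``absent`` returns filler text guaranteed to contain no lexicon term.
    """
    if mention_kind not in _TEMPLATES:
        raise ValueError(f"unknown mention kind {mention_kind!r}")
    template = _TEMPLATES[mention_kind][rng.integers(len(_TEMPLATES[mention_kind]))]
    return template.format(term=term)


def generate_event_time(hazard: float, horizon: float, rng: np.random.Generator) -> tuple:
    """Constant-hazard (exponential) event time, administratively censored.

    Returns ``(time_in_years, observed)``; ``hazard=0`` always censors at
    the horizon.
    """
    if hazard < 0:
        raise ValueError("hazard must be non-negative")
    if hazard == 0:
        return horizon, False
    t = rng.exponential(1.0 / hazard)
    if t > horizon:
        return horizon, False
    return t, True


# ---------------------------------------------------------------------------
# default stated world

_DX_PREV = {
    #                 s1     s2     s3     s4     s5
    "obesity": (0.60, 0.55, 0.45, 0.30, 0.35),
    "type2_diabetes": (0.28, 0.55, 0.25, 0.50, 0.55),
    "hypertension": (0.60, 0.70, 0.40, 0.65, 0.70),
    "hyperlipidemia": (0.30, 0.37, 0.25, 0.21, 0.28),
    "gerd": (0.19, 0.27, 0.13, 0.15, 0.18),
    "asthma": (0.11, 0.22, 0.07, 0.08, 0.10),
    "depression": (0.07, 0.17, 0.05, 0.08, 0.17),
    "anxiety": (0.06, 0.13, 0.04, 0.06, 0.09),
    "tobacco_use": (0.05, 0.20, 0.04, 0.10, 0.29),
    "osa": (0.06, 0.12, 0.05, 0.06, 0.07),
    "vitamin_d_deficiency": (0.14, 0.12, 0.08, 0.08, 0.09),
    "atrial_fibrillation": (0.02, 0.03, 0.01, 0.06, 0.11),
    "uti": (0.04, 0.12, 0.03, 0.05, 0.17),
    "pneumonia": (0.02, 0.05, 0.01, 0.04, 0.10),
    "sepsis": (0.003, 0.02, 0.002, 0.04, 0.25),
    "malignancy": (0.02, 0.03, 0.015, 0.06, 0.15),
    "heart_failure": (0.02, 0.05, 0.01, 0.05, 0.15),
    "copd": (0.03, 0.06, 0.02, 0.05, 0.09),
    "anemia": (0.08, 0.15, 0.05, 0.15, 0.30),
    "hypothyroidism": (0.08, 0.09, 0.07, 0.08, 0.08),
}
_MED_PREV = {
    "metformin": (0.20, 0.35, 0.12, 0.20, 0.20),
    "insulin": (0.08, 0.25, 0.05, 0.15, 0.30),
    "atorvastatin": (0.20, 0.30, 0.12, 0.18, 0.20),
    "omeprazole": (0.18, 0.28, 0.10, 0.15, 0.18),
    "aspirin": (0.15, 0.30, 0.10, 0.20, 0.30),
    "lisinopril": (0.12, 0.25, 0.08, 0.15, 0.18),
    "amlodipine": (0.10, 0.22, 0.07, 0.14, 0.16),
    "metoprolol": (0.08, 0.20, 0.05, 0.15, 0.28),
    "furosemide": (0.04, 0.10, 0.02, 0.10, 0.25),
    "oxycodone": (0.05, 0.15, 0.03, 0.08, 0.20),
    "acetaminophen": (0.10, 0.25, 0.06, 0.12, 0.28),
    "gabapentin": (0.06, 0.14, 0.04, 0.07, 0.10),
    "albuterol": (0.08, 0.18, 0.05, 0.07, 0.10),
    "fluticasone": (0.09, 0.15, 0.06, 0.06, 0.08),
    "pantoprazole": (0.05, 0.10, 0.03, 0.08, 0.20),
    "famotidine": (0.04, 0.10, 0.03, 0.06, 0.15),
}
_LAB_PREV = {
    "ALT": (0.55, 0.75, 0.45, 0.55, 0.70),
    "AST": (0.30, 0.50, 0.20, 0.55, 0.70),
    "platelets": (0.10, 0.30, 0.08, 0.45, 0.55),
    "bilirubin_total": (0.08, 0.25, 0.06, 0.40, 0.60),
    "albumin": (0.08, 0.25, 0.05, 0.35, 0.60),
    "INR": (0.05, 0.20, 0.04, 0.35, 0.55),
    "creatinine": (0.08, 0.20, 0.05, 0.20, 0.40),
    "hemoglobin": (0.10, 0.20, 0.08, 0.25, 0.45),
    "hba1c": (0.25, 0.50, 0.20, 0.45, 0.50),
}
_CPT_PREV = {
    "digestive_surgery": (0.17, 0.40, 0.10, 0.20, 0.50),
    "cardiovascular_surgery": (0.07, 0.15, 0.04, 0.10, 0.31),
    "respiratory_surgery": (0.04, 0.08, 0.03, 0.06, 0.17),
}
_VITAL_PREV = {
    "blood_pressure": (0.40, 0.55, 0.30, 0.45, 0.55),
    "heart_rate": (0.03, 0.08, 0.02, 0.05, 0.15),
    "temperature": (0.02, 0.05, 0.01, 0.03, 0.10),
    "respiratory_rate": (0.01, 0.03, 0.01, 0.02, 0.08),
    "pain": (0.10, 0.25, 0.06, 0.12, 0.30),
}
_HAZARDS = {
    "death": (0.004, 0.015, 0.002, 0.05, 0.30),
    "cirrhosis": (0.002, 0.005, 0.0005, 0.08, 0.10),
    "hcc": (0.0008, 0.002, 0.0003, 0.05, 0.03),
    "ckd": (0.008, 0.03, 0.004, 0.03, 0.06),
    "cvd": (0.015, 0.05, 0.004, 0.04, 0.08),
    "mi": (0.003, 0.02, 0.001, 0.01, 0.03),
}
_DEMOGRAPHICS = {
    # label: (age_mean, age_sd, female_prob, hispanic_prob, meld_mean, meld_sd)
    1: (53.0, 13.0, 0.62, 0.24, 8.0, 2.0),
    2: (50.0, 13.0, 0.52, 0.26, 10.0, 3.0),
    3: (47.0, 13.0, 0.48, 0.10, 7.0, 1.5),
    4: (62.0, 12.0, 0.35, 0.12, 14.0, 4.0),
    5: (65.0, 12.0, 0.45, 0.24, 20.0, 6.0),
}
_MIXING = (0.50, 0.06, 0.37, 0.04, 0.03)


def _prevalences_for(col: int) -> dict:
    prev = {}
    for name, row in _DX_PREV.items():
        prev[f"dx:{name}"] = row[col]
    for name, row in _MED_PREV.items():
        prev[f"med:{name}"] = row[col]
    for name, row in _LAB_PREV.items():
        prev[f"lab:{name}"] = row[col]
    for name, row in _CPT_PREV.items():
        prev[f"cpt:{name}"] = row[col]
    for name, row in _VITAL_PREV.items():
        prev[f"vital:{name}"] = row[col]
    return prev


def default_cohort_config(n_patients: int, seed: int, **overrides) -> CohortConfig:
    """Five-subtype stated world: two large mild subtypes, three small
    sicker ones with much higher death/cirrhosis/HCC hazards."""
    specs = []
    for i, label in enumerate(range(1, 6)):
        age_mean, age_sd, female, hispanic, meld_mean, meld_sd = _DEMOGRAPHICS[label]
        specs.append(
            SubtypeSpec(
                label=label,
                mixing_proportion=_MIXING[i],
                feature_prevalences=_prevalences_for(i),
                outcome_hazards={o: _HAZARDS[o][i] for o in OUTCOMES},
                age_mean=age_mean,
                age_sd=age_sd,
                female_prob=female,
                hispanic_prob=hispanic,
                meld_mean=meld_mean,
                meld_sd=meld_sd,
            )
        )
    return CohortConfig(n_patients=n_patients, seed=seed, subtype_specs=tuple(specs), **overrides)


def separated_cohort_config(
    n_patients: int,
    seed: int,
    k: int = 5,
    p_high: float = 0.95,
    p_low: float = 0.05,
) -> CohortConfig:
    """Well-separated world: every concept's prevalence is ``p_high`` in
    one subtype (round-robin) and ``p_low`` in the rest, so the planted
    partition is recoverable by clustering.  Everyone is phenotype-eligible
    (always-positive steatosis notes, no exclusions)."""
    concepts = sorted(_prevalences_for(0).keys())
    specs = []
    for i in range(k):
        prev = {c: (p_high if j % k == i else p_low) for j, c in enumerate(concepts)}
        specs.append(
            SubtypeSpec(
                label=i + 1,
                mixing_proportion=1.0 / k,
                feature_prevalences=prev,
                outcome_hazards={o: 0.01 for o in OUTCOMES},
                note_mention_profile=(1.0, 0.0, 0.0, 0.0),
            )
        )
    return CohortConfig(
        n_patients=n_patients, seed=seed, subtype_specs=tuple(specs), exclusion_prob=0.0
    )


def noise_cohort_config(n_patients: int, seed: int, k: int = 5) -> CohortConfig:
    """Pure-noise world: all subtypes share identical prevalences, so any
    clustering of the feature matrix is uninformative about the labels."""
    prev = _prevalences_for(0)
    specs = tuple(
        SubtypeSpec(
            label=i + 1,
            mixing_proportion=1.0 / k,
            feature_prevalences=dict(prev),
            outcome_hazards={o: 0.01 for o in OUTCOMES},
            note_mention_profile=(1.0, 0.0, 0.0, 0.0),
        )
        for i in range(k)
    )
    return CohortConfig(n_patients=n_patients, seed=seed, subtype_specs=specs, exclusion_prob=0.0)


# ---------------------------------------------------------------------------
# generation

_DAY = timedelta(days=1)


def _rand_date(rng, start: date, end: date) -> date:
    span = (end - start).days
    return start + int(rng.integers(span + 1)) * _DAY


def _clamp(d: date, lo: date, hi: date) -> date:
    return max(lo, min(d, hi))


def generate_cohort(config: CohortConfig) -> tuple:
    """Generate an :class:`EmrBundle` plus the hidden truth table.

    Deterministic given the config seed.  The truth table (one row per
    patient: subtype label and latent outcome times in years from the
    index date) is returned separately and never appears in the bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    win_start, win_end = config.index_window
    specs = config.subtype_specs
    mixing = np.array([s.mixing_proportion for s in specs])

    patients, codes, meds, labs, vitals, docs, truth = [], [], [], [], [], [], []
    steatosis_terms = ("hepatic steatosis", "steatohepatitis", "fatty liver", "steatosis")

    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        spec = specs[rng.choice(len(specs), p=mixing)]

        sex = "F" if rng.random() < spec.female_prob else "M"
        hispanic = rng.random() < spec.hispanic_prob
        races, rprobs = zip(*sorted(spec.race_probs.items()))
        race = races[rng.choice(len(races), p=np.array(rprobs) / sum(rprobs))]
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.5, 95.0))
        # leave >= ~6 months of the window after the index date
        index_date = _rand_date(rng, win_start, win_end - timedelta(days=215))
        birth_date = index_date - timedelta(days=int(age * 365.25))

        # --- outcome latent times (years from index), death truncates all
        horizon = (win_end - index_date).days / 365.25
        latent = {}
        for outcome in OUTCOMES:
            t, obs = generate_event_time(spec.outcome_hazards.get(outcome, 0.0), horizon, rng)
            latent[outcome] = (t, obs)
        death_t, death_obs = latent["death"]
        death_date = index_date + timedelta(days=round(death_t * 365.25)) if death_obs else None
        record_end = death_date if death_date else win_end

        # --- NAFLD qualification channels
        via_alt = rng.random() < config.alt_rule_prob
        via_icd = rng.random() < config.icd_rule_prob
        if not via_alt and not via_icd:
            via_alt = True
        alt_threshold = 40.0 if sex == "M" else 31.0
        if via_alt:
            # separation = gap - offset >= 200 - 15 > 183 days by construction
            gap = int(rng.integers(200, 500))
            d1 = index_date - gap * _DAY
            d2 = index_date - int(rng.integers(0, 16)) * _DAY
            for d in (d1, d2):
                labs.append(
                    (pid, d, "ALT", "", round(alt_threshold + rng.uniform(5, 80), 1), 7.0, 40.0, "ambulatory")
                )
        if via_icd:
            system = "ICD9" if rng.random() < 0.5 else "ICD10"
            pool = vocab.NAFLD_INCLUSION_ICD9 if system == "ICD9" else vocab.NAFLD_INCLUSION_ICD10
            code = pool[rng.integers(len(pool))]
            d = index_date - int(rng.integers(0, 30)) * _DAY
            codes.append((pid, d, system, code, "ambulatory"))

        # --- steatosis evidence document at the index date
        kind = MENTION_KINDS[rng.choice(4, p=np.array(spec.note_mention_profile))]
        term = steatosis_terms[rng.integers(len(steatosis_terms))]
        doc_type = ("imaging", "note", "pathology")[rng.integers(3)]
        docs.append((pid, index_date, doc_type, generate_note_text(kind, term, rng), kind))

        # --- exclusion triggers (rare by default)
        if rng.random() < config.exclusion_prob:
            which = rng.integers(3)
            d = _clamp(_rand_date(rng, index_date - 400 * _DAY, index_date), birth_date, record_end)
            if which == 0:
                exc = vocab.exclusion_codes()
                row = exc.iloc[rng.integers(len(exc))]
                codes.append((pid, d, row["system"], row["code"], "ambulatory"))
            elif which == 1:
                test = "HBsAg" if rng.random() < 0.5 else "HCV RNA"
                labs.append((pid, d, test, "detected" if test == "HCV RNA" else "reactive", None, None, None, "ambulatory"))
            else:
                med = sorted(vocab.steatogenic_meds())[rng.integers(len(vocab.steatogenic_meds()))]
                meds.append((pid, d, med))

        # --- subtype feature events
        lab_ref = vocab.lab_reference()
        lab_flags = {}
        for concept, p in sorted(spec.feature_prevalences.items()):
            hit = rng.random() < p
            domain, name = concept.split(":", 1)
            if domain == "lab":
                lab_flags[name] = hit
                continue
            if not hit:
                continue
            d = _clamp(
                _rand_date(rng, index_date - 365 * _DAY, min(index_date + 365 * _DAY, record_end)),
                birth_date,
                record_end,
            )
            if domain == "dx":
                icd9, icd10 = vocab.DX_CONCEPTS[name]
                system = "ICD9" if rng.random() < 0.5 else "ICD10"
                setting = "inpatient" if rng.random() < 0.3 else "ambulatory"
                codes.append((pid, d, system, icd9 if system == "ICD9" else icd10, setting))
            elif domain == "med":
                drugs = [dn for dn, ing in vocab.drug_ingredients().items() if ing == name]
                gap2 = int(rng.integers(185, 420))
                d0 = _clamp(d - gap2 * _DAY, birth_date, record_end)
                if (d - d0).days < 184:
                    d = _clamp(d0 + 185 * _DAY, birth_date, record_end)
                meds.append((pid, d0, drugs[rng.integers(len(drugs))]))
                meds.append((pid, d, drugs[rng.integers(len(drugs))]))
            elif domain == "cpt":
                codes.append((pid, d, "CPT", vocab.CPT_CONCEPT_CODES[name], "inpatient"))
            elif domain == "vital":
                if name == "blood_pressure":
                    vitals.append((pid, d, "sbp", round(rng.uniform(135, 180), 0), "mmHg"))
                    vitals.append((pid, d, "dbp", round(rng.uniform(85, 110), 0), "mmHg"))
                elif name == "temperature":
                    vitals.append((pid, d, "temperature", round(rng.uniform(102.5, 105.0), 1), "F"))
                elif name == "heart_rate":
                    vitals.append((pid, d, "heart_rate", round(rng.uniform(131, 170), 0), "bpm"))
                elif name == "respiratory_rate":
                    vitals.append((pid, d, "respiratory_rate", round(rng.uniform(41, 55), 0), "bpm"))
                elif name == "pain":
                    vitals.append((pid, d, "pain", float(rng.integers(9, 11)), "scale"))

        # baseline labs at index (support FIB-4); abnormality per lab flag
        for test in ("ALT", "AST", "platelets", "bilirubin_total", "albumin", "INR"):
            lo, hi = lab_ref[test]
            abnormal = lab_flags.get(test, False)
            direction = vocab.LAB_ABNORMAL_DIRECTION[test]
            if abnormal:
                value = hi * rng.uniform(1.2, 3.0) if direction == "high" else lo * rng.uniform(0.3, 0.9)
            else:
                value = rng.uniform(lo * 1.05, hi * 0.95)
            labs.append((pid, index_date, test, "", round(float(value), 2), lo, hi, "ambulatory"))
        for test in ("creatinine", "hemoglobin", "hba1c"):
            if not lab_flags.get(test, False):
                continue
            lo, hi = lab_ref[test]
            direction = vocab.LAB_ABNORMAL_DIRECTION[test]
            value = hi * rng.uniform(1.2, 2.5) if direction == "high" else lo * rng.uniform(0.5, 0.9)
            d = _clamp(_rand_date(rng, index_date - 365 * _DAY, min(index_date + 365 * _DAY, record_end)), birth_date, record_end)
            labs.append((pid, d, test, "", round(float(value), 2), lo, hi, "ambulatory"))

        # normal background vitals
        for _ in range(int(rng.integers(1, 3))):
            d = _clamp(_rand_date(rng, index_date - 365 * _DAY, min(index_date + 200 * _DAY, record_end)), birth_date, record_end)
            vitals.append((pid, d, "sbp", round(rng.uniform(100, 128), 0), "mmHg"))
            vitals.append((pid, d, "dbp", round(rng.uniform(60, 78), 0), "mmHg"))
            vitals.append((pid, d, "heart_rate", round(rng.uniform(60, 100), 0), "bpm"))

        # MELD note
        if rng.random() < config.meld_note_prob:
            meld = int(np.clip(round(rng.normal(spec.meld_mean, spec.meld_sd)), 6, 40))
            d = _clamp(index_date + int(rng.integers(0, 60)) * _DAY, birth_date, record_end)
            docs.append((pid, d, "note", f"MELD score: {meld}. Hepatology follow-up arranged.", "absent"))

        # --- observed (non-death) outcome events before death
        for outcome in ("cirrhosis", "hcc", "ckd", "cvd", "mi"):
            t, obs = latent[outcome]
            if not obs or (death_obs and t >= death_t):
                continue
            d = index_date + timedelta(days=round(t * 365.25))
            if outcome == "cirrhosis":
                docs.append((pid, d, ("note", "imaging", "pathology")[rng.integers(3)],
                             generate_note_text("positive", "cirrhosis", rng), "positive"))
            else:
                icd9, icd10 = vocab.OUTCOME_EVENT_CODES[outcome]
                system = "ICD9" if rng.random() < 0.5 else "ICD10"
                codes.append((pid, d, system, icd9 if system == "ICD9" else icd10, "inpatient"))
                if outcome == "ckd" and rng.random() < 0.5:
                    codes.append((pid, d, "CPT", vocab.CPT_DIALYSIS_CODE, "inpatient"))

        if death_obs and rng.random() < config.death_note_prob:
            docs.append((pid, death_date, "note", "Patient expired. Family notified.", "positive"))

        patients.append((pid, birth_date, sex, race, "Hispanic" if hispanic else "Not Hispanic",
                         death_date))
        row = {"patient_id": pid, "subtype": spec.label, "index_date": index_date}
        for outcome in OUTCOMES:
            row[f"{outcome}_time_years"] = latent[outcome][0]
            row[f"{outcome}_observed"] = latent[outcome][1]
        truth.append(row)

    bundle = EmrBundle(
        patients=pd.DataFrame(
            patients, columns=["patient_id", "birth_date", "sex", "race", "ethnicity", "death_date"]
        ),
        code_events=pd.DataFrame(
            codes, columns=["patient_id", "date", "system", "code", "setting"]
        ),
        med_orders=pd.DataFrame(meds, columns=["patient_id", "date", "drug_name"]),
        lab_results=pd.DataFrame(
            labs,
            columns=["patient_id", "date", "test_name", "value_text", "value_num", "ref_low", "ref_high", "setting"],
        ),
        vitals=pd.DataFrame(vitals, columns=["patient_id", "date", "kind", "value", "unit"]),
        documents=pd.DataFrame(
            docs, columns=["patient_id", "date", "doc_type", "text", "truth_mention_kind"]
        ),
    )
    # the per-document truth column supports NLP recovery checks; keep it
    # out of the bundle proper
    doc_truth = bundle.documents[["patient_id", "date", "doc_type", "truth_mention_kind"]].copy()
    bundle.documents = bundle.documents.drop(columns=["truth_mention_kind"])
    truth_df = pd.DataFrame(truth)
    for tbl in bundle.tables().values():
        for col in tbl.columns:
            if col.endswith("date") or col == "date":
                tbl[col] = pd.to_datetime(tbl[col])
    truth_df["index_date"] = pd.to_datetime(truth_df["index_date"])
    doc_truth["date"] = pd.to_datetime(doc_truth["date"])
    return bundle, truth_df, doc_truth
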