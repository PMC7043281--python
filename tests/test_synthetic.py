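"""Generator contracts: determinism, planted structure, closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nafld_subtypes import io as bundle_io
from nafld_subtypes.synthetic import (
    CohortConfig,
    SubtypeSpec,
    default_cohort_config,
    generate_cohort,
    generate_event_time,
    generate_note_text,
)
from nafld_subtypes.textmining import STEATOSIS_LEXICON, find_mentions


def test_patient_count_and_determinism(tmp_path):
    config = default_cohort_config(100, seed=1)
    b1, t1, _ = generate_cohort(config)
    b2, t2, _ = generate_cohort(config)
    assert len(b1.patients) == 100
    pd.testing.assert_frame_equal(t1, t2)
    d1 = bundle_io.write_bundle(b1, tmp_path / "a")
    d2 = bundle_io.write_bundle(b2, tmp_path / "b")
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_invalid_config_rejected():
    spec = SubtypeSpec(1, 1.0, {"dx:obesity": 1.4}, {"death": 0.01})
    with pytest.raises(ValueError, match="outside"):
        CohortConfig(10, 0, subtype_specs=(spec,)).validate()
    bad_hazard = SubtypeSpec(1, 1.0, {"dx:obesity": 0.4}, {"death": -0.01})
    with pytest.raises(ValueError, match="hazard"):
        CohortConfig(10, 0, subtype_specs=(bad_hazard,)).validate()
    with pytest.raises(ValueError, match="sum"):
        base = default_cohort_config(10, 0)
        CohortConfig(10, 0, subtype_specs=base.subtype_specs[:2]).validate()


def test_mixing_proportions_within_binomial_interval():
    """4 subtypes at (0.4, 0.3, 0.2, 0.1), n=5000: every empirical count
    lies inside the exact binomial 99% interval."""
    base = default_cohort_config(10, 0)
    props = (0.4, 0.3, 0.2, 0.1)
    specs = tuple(
        SubtypeSpec(
            label=i + 1,
            mixing_proportion=props[i],
            feature_prevalences=base.subtype_specs[i].feature_prevalences,
            outcome_hazards=base.subtype_specs[i].outcome_hazards,
        )
        for i in range(4)
    )
    n = 5000
    _, truth, _ = generate_cohort(CohortConfig(n, seed=7, subtype_specs=specs))
    counts = truth["subtype"].value_counts()
    for i, p in enumerate(props, start=1):
        lo, hi = sps.binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts[i] <= hi


def test_per_subtype_dx_frequencies_track_prevalences():
    """Emitted diagnosis-code frequencies converge to the planted
    Bernoulli prevalences (within 3 binomial SEs per subtype)."""
    from nafld_subtypes import vocab

    config = default_cohort_config(3000, seed=5)
    bundle, truth, _ = generate_cohort(config)
    subtype_of = truth.set_index("patient_id")["subtype"]
    codes = bundle.code_events
    for spec in config.subtype_specs:
        members = subtype_of[subtype_of == spec.label].index
        n = len(members)
        sub_codes = codes[codes["patient_id"].isin(members)]
        for concept in ("dx:obesity", "dx:type2_diabetes", "dx:sepsis"):
            p = spec.feature_prevalences[concept]
            icd9, icd10 = vocab.DX_CONCEPTS[concept.split(":")[1]]
            has = sub_codes[sub_codes["code"].isin((icd9, icd10))]["patient_id"].nunique()
            se = np.sqrt(max(p * (1 - p), 1e-9) / n)
            assert abs(has / n - p) < max(3 * se, 5 / n), (spec.label, concept)


def test_truth_never_leaks_into_bundle():
    bundle, truth, _ = generate_cohort(default_cohort_config(50, seed=3))
    for name, tbl in bundle.tables().items():
        assert "subtype" not in tbl.columns, name
        assert not any("truth" in c for c in tbl.columns), name


@pytest.mark.parametrize(
    "kind,term",
    [("positive", "hepatic steatosis"), ("negated", "steatohepatitis"), ("family", "fatty liver")],
)
def test_note_text_polarity_matches_kind(kind, term):
    rng = np.random.default_rng(0)
    for _ in range(20):
        text = generate_note_text(kind, term, rng)
        mentions = find_mentions(text, STEATOSIS_LEXICON)
        assert len(mentions) == 1
        expected = "family_or_false_positive" if kind == "family" else kind
        assert mentions[0].polarity == expected, text


def test_note_text_absent_has_no_lexicon_match():
    rng = np.random.default_rng(0)
    for _ in range(10):
        text = generate_note_text("absent", "fatty liver", rng)
        assert find_mentions(text, STEATOSIS_LEXICON) == []


def test_event_time_zero_hazard_always_censors():
    rng = np.random.default_rng(0)
    assert generate_event_time(0.0, 10.0, rng) == (10.0, False)
    with pytest.raises(ValueError):
        generate_event_time(-0.1, 10.0, rng)


def test_event_time_observed_fraction_closed_form():
    """hazard 0.5/yr over 10 yr: observed fraction ~ 1 - exp(-5)."""
    rng = np.random.default_rng(11)
    n = 20000
    observed = sum(generate_event_time(0.5, 10.0, rng)[1] for _ in range(n))
    expect = 1 - np.exp(-0.5 * 10)
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(observed / n - expect) < 3 * se


def test_event_time_reproducible_with_seed():
    a = generate_event_time(0.3, 5.0, np.random.default_rng(42))
    b = generate_event_time(0.3, 5.0, np.random.default_rng(42))
    assert a == b


def test_bundle_date_invariants():
    bundle, _, _ = generate_cohort(default_cohort_config(200, seed=9))
    pts = bundle.patients.set_index("patient_id")
    known = set(pts.index)
    for name, tbl in bundle.tables().items():
        if name == "patients":
            continue
        assert set(tbl["patient_id"]) <= known, name
        merged = tbl.merge(pts[["birth_date", "death_date"]], on="patient_id")
        assert (merged["date"] >= merged["birth_date"]).all(), name
        died = merged[merged["death_date"].notna()]
        assert (died["date"] <= died["death_date"]).all(), name
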