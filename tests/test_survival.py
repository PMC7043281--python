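"""Survival estimators against hand computations and independent fitters."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from conftest import make_bundle
from nafld_subtypes.survival import (
    build_covariates,
    build_outcome_table,
    censoring_km,
    cif_at,
    cox_ph,
    cumulative_incidence,
    fib4_category,
    fib4_score,
    fine_gray,
    kaplan_meier,
    km_survival_at,
    simulate_two_arm_exponential,
)


def test_km_hand_fixture():
    """times {8 event, 5 censor, 12 event}: S(8)=1/2 (risk set {8,12}), S(12)=0."""
    km = kaplan_meier([8, 5, 12], [True, False, True])
    assert km_survival_at(km, 7.9) == 1.0
    assert km_survival_at(km, 8) == 0.5
    assert km_survival_at(km, 12) == 0.0


def test_km_no_events_and_ecdf_reduction():
    km = kaplan_meier([1, 2, 3], [False, False, False])
    assert km.empty  # S stays 1 everywhere
    times = [1.0, 2.0, 3.0, 4.0]
    km2 = kaplan_meier(times, [True] * 4)
    for t, s in zip(times, [0.75, 0.5, 0.25, 0.0]):
        assert km_survival_at(km2, t) == pytest.approx(s)


def test_aalen_johansen_hand_fixture():
    """{2 type1, 4 type2, 6 censor}: CIF1(inf)=1/3, CIF2(inf)=(2/3)(1/2)=1/3."""
    cifs = cumulative_incidence([2, 4, 6], [1, 2, 0])
    assert cif_at(cifs[1], 100) == pytest.approx(1 / 3)
    assert cif_at(cifs[2], 100) == pytest.approx(1 / 3)


def test_cif_reduces_to_one_minus_km_without_competing():
    rng = np.random.default_rng(2)
    t = rng.exponential(5, size=60)
    e = rng.random(60) < 0.7
    cifs = cumulative_incidence(t, e.astype(int))
    km = kaplan_meier(t, e)
    for tt in np.quantile(t, [0.2, 0.5, 0.8]):
        assert cif_at(cifs[1], tt) == pytest.approx(1 - km_survival_at(km, tt))


def test_cif_conservation_complete_data():
    rng = np.random.default_rng(3)
    t = rng.exponential(5, size=50)
    codes = rng.integers(1, 3, size=50)  # complete: no censoring
    cifs = cumulative_incidence(t, codes)
    km_all = kaplan_meier(t, np.ones(50, dtype=bool))
    for tt in sorted(t):
        total = cif_at(cifs[1], tt) + cif_at(cifs[2], tt) + km_survival_at(km_all, tt)
        assert total == pytest.approx(1.0)
    # CIFs are non-decreasing and bounded
    for k in (1, 2):
        assert (np.diff(cifs[k]["cif"]) >= 0).all()
        assert cifs[k]["cif"].iloc[-1] <= 1.0


def test_cox_symmetric_groups_give_null_hr():
    t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    e = np.ones(8, bool)
    x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
    fit = cox_ph(t, e, x)
    assert fit.summary["hr"][0] == pytest.approx(1.0, abs=1e-8)


def test_cox_matches_brute_force_partial_likelihood():
    """6 subjects, no ties: Newton solution equals direct numerical
    maximization of the written-out partial likelihood."""
    t = np.array([1.0, 2.5, 3.1, 4.7, 5.2, 6.9])
    e = np.array([1, 1, 0, 1, 1, 0], bool)
    x = np.array([0.5, -1.0, 0.3, 1.2, -0.4, 0.8])

    def neg_pl(beta):
        ll = 0.0
        for i in range(6):
            if not e[i]:
                continue
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    brute = minimize(lambda b: neg_pl(b[0]), [0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    fit = cox_ph(t, e, x)
    assert fit.converged
    assert fit.summary["coef"][0] == pytest.approx(brute.x[0], abs=1e-6)
    assert -fit.log_likelihood == pytest.approx(brute.fun, abs=1e-8)


def test_cox_matches_lifelines_with_ties():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(3)
    n = 150
    x = rng.normal(size=(n, 2))
    t = np.ceil(rng.exponential(10 * np.exp(-0.5 * x[:, 0] + 0.3 * x[:, 1])))
    e = rng.random(n) < 0.8
    fit = cox_ph(t, e, x, ["a", "b"])
    frame = pd.DataFrame({"t": t, "e": e.astype(int), "a": x[:, 0], "b": x[:, 1]})
    ref = CoxPHFitter().fit(frame, "t", "e")
    np.testing.assert_allclose(fit.summary["coef"], ref.params_.values, atol=1e-5)
    np.testing.assert_allclose(fit.summary["se"], ref.standard_errors_.values, atol=1e-5)


def test_cox_requires_events():
    with pytest.raises(ValueError, match="no events"):
        cox_ph([1.0, 2.0], [False, False], [[0.0], [1.0]])


def test_fine_gray_reduces_to_cox_without_competing_events():
    rng = np.random.default_rng(7)
    n = 100
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.6 * x))
    e = (rng.random(n) < 0.7).astype(int)
    fg = fine_gray(t, e, x)
    cx = cox_ph(t, e == 1, x)
    assert fg.summary["coef"][0] == pytest.approx(cx.summary["coef"][0], abs=1e-6)


def test_fine_gray_ipcw_weights_before_any_censoring():
    """With no censoring at all, the censoring KM is 1 and competing
    subjects keep weight ratio 1."""
    t = np.array([1.0, 2.0, 3.0, 4.0])
    codes = np.array([1, 2, 1, 2])
    g = censoring_km(t, codes)
    assert g.empty  # no censoring events -> G = 1 everywhere


def test_hr_invariant_to_time_scaling():
    rng = np.random.default_rng(12)
    t, e, x = simulate_two_arm_exponential(400, 2.0, 0.3, 5.0, rng)
    a = cox_ph(t, e, x).summary["coef"][0]
    b = cox_ph(t * 3.7, e, x).summary["coef"][0]
    assert a == pytest.approx(b, abs=1e-9)
    codes = np.where(e, 1, 0)
    fa = fine_gray(t, codes, x).summary["coef"][0]
    fb = fine_gray(t * 3.7, codes, x).summary["coef"][0]
    assert fa == pytest.approx(fb, abs=1e-9)


@pytest.mark.parametrize(
    "age,ast,alt,plt,cat",
    [
        (60, 40, 36, 100, "high"),  # 60*40/(100*6) = 4.0
        (50, 20, 25, 250, "low"),
        (60, 40, 36, None, "missing"),
        (60, -1, 36, 100, "missing"),
    ],
)
def test_fib4(age, ast, alt, plt, cat):
    assert fib4_category(age, ast, alt, plt) == cat


def test_fib4_boundary_indeterminate():
    # solve for platelets giving exactly 1.3: 60*40/(p*6) = 1.3
    p = 60 * 40 / (1.3 * 6)
    assert fib4_score(60, 40, 36, p) == pytest.approx(1.3)
    assert fib4_category(60, 40, 36, p) == "indeterminate"


def _outcome_bundle():
    """One patient per outcome-table branch; NAFLD date 2015-01-01."""
    patients = [
        ("prev", "1960-01-01", "M", "White", "Not Hispanic", None),
        ("evt", "1960-01-01", "M", "White", "Not Hispanic", "2016-11-26"),  # +695d
        ("cmp", "1960-01-01", "M", "White", "Not Hispanic", "2015-10-28"),  # +300d
        ("cens", "1960-01-01", "M", "White", "Not Hispanic", None),
    ]
    codes = [
        ("prev", "2015-03-02", "ICD9", "155.0", "inpatient"),  # HCC +60d -> prevalent
        ("evt", "2016-02-05", "ICD10", "N18.9", "inpatient"),  # CKD +400d
    ]
    bundle = make_bundle(patients, codes)
    decisions = pd.DataFrame(
        {
            "patient_id": ["prev", "evt", "cmp", "cens"],
            "eligible": True,
            "nafld_date": pd.Timestamp("2015-01-01"),
            "failed_rules": "",
        }
    )
    return bundle, decisions


def test_outcome_table_branches():
    bundle, decisions = _outcome_bundle()
    table = build_outcome_table(bundle, decisions).set_index(["patient_id", "outcome"])

    hcc_prev = table.loc[("prev", "hcc")]
    assert hcc_prev["prevalent"] and hcc_prev["event"] == 1 and hcc_prev["time_days"] == 60

    ckd_evt = table.loc[("evt", "ckd")]
    assert not ckd_evt["prevalent"] and ckd_evt["event"] == 1 and ckd_evt["time_days"] == 400

    ckd_cmp = table.loc[("cmp", "ckd")]
    assert ckd_cmp["event"] == 2 and ckd_cmp["time_days"] == 300  # death competes

    death_row = table.loc[("cmp", "death")]
    assert death_row["event"] == 1 and death_row["time_days"] == 300

    cens_row = table.loc[("cens", "ckd")]
    admin = (pd.Timestamp("2019-01-31") - pd.Timestamp("2015-01-01")).days
    assert cens_row["event"] == 0 and cens_row["time_days"] == admin


def test_covariates_hispanic_precedence_and_reference():
    bundle, decisions = _outcome_bundle()
    bundle.patients.loc[0, "ethnicity"] = "Hispanic"
    assignment = {"prev": 2, "evt": 1, "cmp": 1, "cens": 1}
    cov = build_covariates(bundle, decisions, assignment)
    assert cov.loc["prev", "race_hispanic"] == 1
    assert "subtype_1" not in cov.columns  # subtype 1 is the reference
    assert cov.loc["prev", "subtype_2"] == 1
    assert cov.loc["evt", "subtype_2"] == 0
    assert cov.loc["prev", "fib4_missing"] == 1  # no labs anywhere
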