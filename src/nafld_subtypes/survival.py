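"""Time-to-event analysis of subtype outcomes under competing risks.

Outcomes (death, cirrhosis, HCC, CKD, CVD, MI) are identified from ICD
code prefixes, CPT ranges, or positive NLP mentions.  Survival time runs
from the NAFLD diagnosis date to the earliest evidence of the outcome;
evidence on/before day 183 after diagnosis marks a *prevalent* case,
which is excluded from model fitting.  Death before the outcome is a
competing event; otherwise patients are administratively censored at
2019-01-31 (optionally at last contact).

Estimators:

* Kaplan-Meier product-limit curve (overall survival);
* Aalen-Johansen cumulative incidence per event type,
  ``CIF_k(t) = sum_{t_i <= t} S(t_i-) d_ki / n_i`` with S the all-cause KM;
* Cox proportional hazards via Newton-Raphson on the partial likelihood
  (Efron tie correction by default, Breslow available);
* Fine-Gray proportional subdistribution hazards: competing-event
  subjects stay in the risk set weighted by the censoring-distribution
  Kaplan-Meier (IPCW), Breslow ties, Newton optimization.

The Cox/Fine-Gray engine is hand-rolled because no installed package
fits Fine-Gray regression; lifelines is used as an independent
cross-check in the test suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .synthetic import EmrBundle
from .textmining import CIRRHOSIS_LEXICON, DEATH_LEXICON, find_mentions

ADMIN_CENSOR_DATE = date(2019, 1, 31)
PREVALENT_WINDOW_DAYS = 183  # "prior to or within 6 months", inclusive

CENSORED, EVENT, COMPETING_DEATH = 0, 1, 2


@dataclass(frozen=True)
class OutcomeDefinition:
    """How one outcome is recognised in the record."""

    name: str
    icd9_prefixes: tuple = ()
    icd10_prefixes: tuple = ()
    cpt_range: tuple | None = None  # (low, high) inclusive
    lexicon: object = None

    def __post_init__(self):
        if not (self.icd9_prefixes or self.icd10_prefixes or self.cpt_range or self.lexicon):
            raise ValueError(f"outcome {self.name}: no identification channel")


DEFAULT_OUTCOME_DEFINITIONS = (
    OutcomeDefinition(
        "hcc",
        icd9_prefixes=("155.0", "155.2"),
        icd10_prefixes=("C22.0", "C22.7", "C22.8", "C22.9"),
    ),
    OutcomeDefinition("cirrhosis", lexicon=CIRRHOSIS_LEXICON),
    OutcomeDefinition(
        "ckd",
        icd9_prefixes=("585", "586"),
        icd10_prefixes=("N18", "N19"),
        cpt_range=(90935, 90999),
    ),
    OutcomeDefinition(
        "cvd",
        icd9_prefixes=("410", "411", "412", "413", "414"),
        icd10_prefixes=("I20", "I21", "I22", "I23", "I24", "I25"),
    ),
    OutcomeDefinition("mi", icd9_prefixes=("410",), icd10_prefixes=("I21", "I22")),
)


@dataclass
class HazardModelFit:
    model: str  # "cox" | "fine_gray"
    summary: pd.DataFrame  # covariate, coef, se, hr, ci_lower, ci_upper, p
    converged: bool
    n: int
    n_events: int
    log_likelihood: float
    n_iter: int

    def coef(self, name: str) -> float:
        return float(self.summary.set_index("covariate").loc[name, "coef"])


# ---------------------------------------------------------------------------
# nonparametric estimators


def kaplan_meier(times, observed) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a step function as a DataFrame (time, n_at_risk, n_events,
    survival); at tied times events precede censorings, per convention.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed).astype(bool)
    if len(times) == 0:
        raise ValueError("need at least one observation")
    out = []
    s = 1.0
    for t in np.unique(times[observed]):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & observed).sum())
        s *= 1.0 - d / n_risk
        out.append((float(t), n_risk, d, s))
    return pd.DataFrame(out, columns=["time", "n_at_risk", "n_events", "survival"])


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """Right-continuous evaluation of a kaplan_meier curve at time t."""
    prior = curve[curve["time"] <= t]
    return 1.0 if prior.empty else float(prior["survival"].iloc[-1])


def cumulative_incidence(times, codes) -> dict:
    """Aalen-Johansen cumulative incidence functions per event type.

    ``codes``: 0 censored, k >= 1 an event of type k.  Returns
    {k: DataFrame(time, cif)} with right-continuous non-decreasing steps.
    """
    times = np.asarray(times, dtype=float)
    codes = np.asarray(codes, dtype=int)
    event_types = sorted(set(codes[codes > 0].tolist()))
    cif = {k: [] for k in event_types}
    totals = {k: 0.0 for k in event_types}
    s_prev = 1.0
    for t in np.unique(times[codes > 0]):
        n_risk = int((times >= t).sum())
        here = times == t
        d_all = int((here & (codes > 0)).sum())
        for k in event_types:
            d_k = int((here & (codes == k)).sum())
            totals[k] += s_prev * d_k / n_risk
            cif[k].append((float(t), totals[k]))
        s_prev *= 1.0 - d_all / n_risk
    return {k: pd.DataFrame(v, columns=["time", "cif"]) for k, v in cif.items()}


def cif_at(curve: pd.DataFrame, t: float) -> float:
    prior = curve[curve["time"] <= t]
    return 0.0 if prior.empty else float(prior["cif"].iloc[-1])


# ---------------------------------------------------------------------------
# Newton engine for (weighted) partial likelihoods


def _newton(negloglik_grad_hess, beta0, max_iter=100, tol=1e-10):
    beta = beta0.copy()
    nll, grad, hess = negloglik_grad_hess(beta)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, nll, hess, False, it
        # step-halving line search on the negative log-likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta - factor * step
            nll_new, grad_new, hess_new = negloglik_grad_hess(cand)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-14:
                break
            factor /= 2.0
        else:
            return beta, nll, hess, False, it
        delta = np.abs(nll - nll_new)
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
        if delta < tol and np.max(np.abs(grad)) < 1e-6:
            return beta, nll, hess, True, it
    return beta, nll, hess, False, max_iter


def _cox_nll(beta, X, times, events, ties):
    """Negative log partial likelihood with gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    Xs, ts, es, ws = X[order], times[order], events[order], w[order]
    s0 = np.cumsum(ws)
    s1 = np.cumsum(ws[:, None] * Xs, axis=0)
    s2 = np.cumsum(ws[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0)
    nll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = n - 1
    while i >= 0:
        t = ts[i]
        j = i
        while j >= 0 and ts[j] == t:
            j -= 1
        block = slice(j + 1, i + 1)  # all subjects with this time
        dead = np.flatnonzero(es[block]) + j + 1
        d = len(dead)
        if d:
            S0, S1, S2 = s0[i], s1[i], s2[i]
            nll -= eta[order][dead].sum()
            grad_d = Xs[dead].sum(axis=0)
            if ties == "efron" and d > 1:
                s0d = ws[dead].sum()
                s1d = (ws[dead, None] * Xs[dead]).sum(axis=0)
                s2d = (ws[dead, None, None] * Xs[dead][:, :, None] * Xs[dead][:, None, :]).sum(axis=0)
                for r in range(d):
                    f = r / d
                    phi0 = S0 - f * s0d
                    phi1 = S1 - f * s1d
                    phi2 = S2 - f * s2d
                    nll += np.log(phi0)
                    grad_d = grad_d - phi1 / phi0
                    hess += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
            else:  # breslow
                nll += d * np.log(S0)
                grad_d = grad_d - d * S1 / S0
                hess += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            grad -= grad_d
        i = j
    return nll, grad, hess


def cox_ph(
    times,
    events,
    X,
    covariate_names=None,
    ties: str = "efron",
) -> HazardModelFit:
    """Cox proportional hazards by Newton-Raphson.

    ``events`` is boolean (or 0/1).  Standard errors come from the
    inverse observed information; 95% CIs are normal on the log scale.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if events.sum() == 0:
        raise ValueError("no events; Cox model is undefined")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    names = list(covariate_names) if covariate_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    beta, nll, hess, converged, n_iter = _newton(
        lambda b: _cox_nll(b, X, times, events, ties), np.zeros(X.shape[1])
    )
    return _fit_summary("cox", beta, hess, names, converged, len(times), int(events.sum()), -nll, n_iter)


def _fit_summary(model, beta, hess, names, converged, n, n_events, loglik, n_iter):
    from scipy import stats as sps

    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        converged = False
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # separation -> infinite CI, reported as such
        summary = pd.DataFrame(
            {
                "covariate": names,
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - 1.96 * se),
                "ci_upper": np.exp(beta + 1.96 * se),
                "p": p,
            }
        )
    return HazardModelFit(
        model=model,
        summary=summary,
        converged=converged,
        n=n,
        n_events=n_events,
        log_likelihood=loglik,
        n_iter=n_iter,
    )


def censoring_km(times, codes) -> pd.DataFrame:
    """Kaplan-Meier of the censoring distribution G (codes 0 = 'event')."""
    times = np.asarray(times, dtype=float)
    codes = np.asarray(codes, dtype=int)
    return kaplan_meier(times, codes == 0)


def _g_minus(curve: pd.DataFrame, t: float) -> float:
    """Left-limit G(t-) of the censoring KM."""
    prior = curve[curve["time"] < t]
    return 1.0 if prior.empty else float(prior["survival"].iloc[-1])


def fine_gray(
    times,
    codes,
    X,
    covariate_names=None,
) -> HazardModelFit:
    """Fine-Gray subdistribution-hazard regression (event type 1).

    Subjects with the competing event (code 2) remain in the risk set
    after their event time, down-weighted by the IPCW ratio
    ``G(t-)/G(T_i-)`` where G is the Kaplan-Meier estimate of the
    censoring distribution.  Ties are handled Breslow-style; with no
    competing events and no ties this reduces exactly to Cox.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    codes = np.asarray(codes, dtype=int)
    if not set(codes.tolist()) <= {0, 1, 2}:
        raise ValueError("event codes must be 0 (censored), 1 (event), 2 (competing)")
    if (codes == 1).sum() == 0:
        raise ValueError("no type-1 events; Fine-Gray model is undefined")
    names = list(covariate_names) if covariate_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    g_curve = censoring_km(times, codes)
    event_times = np.unique(times[codes == 1])
    E, n = len(event_times), len(times)
    W = np.zeros((E, n))
    g_at = np.array([_g_minus(g_curve, t) for t in event_times])
    g_own = np.array([_g_minus(g_curve, t) for t in times])
    for j, t in enumerate(event_times):
        natural = times >= t
        W[j, natural] = 1.0
        late = (codes == 2) & (times < t)
        with np.errstate(divide="ignore", invalid="ignore"):
            W[j, late] = np.where(g_own[late] > 0, g_at[j] / g_own[late], 0.0)
    deaths = [np.flatnonzero((times == t) & (codes == 1)) for t in event_times]

    def nll_grad_hess(beta):
        eta = X @ beta
        w = np.exp(eta)
        Wexp = W * w[None, :]
        S0 = Wexp.sum(axis=1)
        S1 = Wexp @ X
        S2 = np.einsum("ji,ip,iq->jpq", Wexp, X, X)
        nll, grad = 0.0, np.zeros(X.shape[1])
        hess = np.zeros((X.shape[1], X.shape[1]))
        for j in range(E):
            dj = deaths[j]
            d = len(dj)
            nll -= eta[dj].sum() - d * np.log(S0[j])
            grad -= X[dj].sum(axis=0) - d * S1[j] / S0[j]
            hess += d * (S2[j] / S0[j] - np.outer(S1[j], S1[j]) / S0[j] ** 2)
        return nll, grad, hess

    beta, nll, hess, converged, n_iter = _newton(nll_grad_hess, np.zeros(X.shape[1]))
    return _fit_summary(
        "fine_gray", beta, hess, names, converged, n, int((codes == 1).sum()), -nll, n_iter
    )


# ---------------------------------------------------------------------------
# FIB-4


def fib4_score(age: float, ast: float, alt: float, platelets: float) -> float | None:
    """FIB-4 = age * AST / (platelets * sqrt(ALT)); None on missing or
    non-positive inputs.  Platelets in 10^9/L (so ~150-400)."""
    vals = (age, ast, alt, platelets)
    if any(v is None or pd.isna(v) or v <= 0 for v in vals):
        return None
    return float(age * ast / (platelets * np.sqrt(alt)))


def fib4_category(age, ast, alt, platelets) -> str:
    """low (< 1.3) / indeterminate (1.3-2.67, bounds inclusive) /
    high (> 2.67) / missing."""
    score = fib4_score(age, ast, alt, platelets)
    if score is None:
        return "missing"
    if score < 1.3:
        return "low"
    if score <= 2.67:
        return "indeterminate"
    return "high"


# ---------------------------------------------------------------------------
# outcome tables from a bundle


def _as_date(value):
    if isinstance(value, pd.Timestamp):
        return value.date()
    return value


def _earliest_evidence(defn: OutcomeDefinition, codes: pd.DataFrame, docs: pd.DataFrame):
    dates = []
    if not codes.empty:
        if defn.icd9_prefixes:
            m = codes[(codes["system"] == "ICD9")]
            m = m[m["code"].astype(str).str.startswith(defn.icd9_prefixes)]
            dates.extend(m["date"].tolist())
        if defn.icd10_prefixes:
            m = codes[(codes["system"] == "ICD10")]
            m = m[m["code"].astype(str).str.startswith(defn.icd10_prefixes)]
            dates.extend(m["date"].tolist())
        if defn.cpt_range:
            lo, hi = defn.cpt_range
            cpt = codes[codes["system"] == "CPT"]
            numeric = pd.to_numeric(cpt["code"], errors="coerce")
            dates.extend(cpt.loc[(numeric >= lo) & (numeric <= hi), "date"].tolist())
    if defn.lexicon is not None and not docs.empty:
        for row in docs.itertuples():
            for mention in find_mentions(row.text, defn.lexicon):
                if mention.polarity == "positive":
                    dates.append(row.date)
                    break
    return min((_as_date(d) for d in dates), default=None)


def _death_evidence(recorded_death, docs: pd.DataFrame):
    dates = []
    if recorded_death is not None and not pd.isna(recorded_death):
        dates.append(_as_date(recorded_death))
    if not docs.empty:
        for row in docs.itertuples():
            for mention in find_mentions(row.text, DEATH_LEXICON):
                if mention.polarity == "positive":
                    dates.append(_as_date(row.date))
                    break
    return min(dates, default=None)


def build_outcome_table(
    bundle: EmrBundle,
    decisions: pd.DataFrame,
    outcome_defs: tuple = DEFAULT_OUTCOME_DEFINITIONS,
    admin_censor: date = ADMIN_CENSOR_DATE,
    censor_at_last_contact: bool = False,
) -> pd.DataFrame:
    """Per patient-outcome time-to-event rows for the eligible cohort.

    Columns: patient_id, outcome, time_days, event (0/1/2), prevalent.
    Death rows use event 1 for death; other outcomes use 2 for death
    before the outcome.  Prevalent rows (evidence on/before NAFLD date +
    183 days, including evidence before diagnosis) are flagged and must
    be excluded from fitting.
    """
    elig = decisions[decisions["eligible"]]
    codes_by = dict(iter(bundle.code_events.groupby("patient_id", sort=False)))
    docs_by = dict(iter(bundle.documents.groupby("patient_id", sort=False)))
    empty_codes = bundle.code_events.iloc[0:0]
    empty_docs = bundle.documents.iloc[0:0]
    patients = bundle.patients.set_index("patient_id")

    last_contact = {}
    if censor_at_last_contact:
        for name, tbl in bundle.tables().items():
            if name == "patients" or tbl.empty:
                continue
            for pid, d in tbl.groupby("patient_id")["date"].max().items():
                cur = last_contact.get(pid)
                dd = _as_date(d)
                if cur is None or dd > cur:
                    last_contact[pid] = dd

    rows = []
    for dec in elig.itertuples():
        pid = dec.patient_id
        nafld = _as_date(dec.nafld_date)
        prow = patients.loc[pid]
        pcodes = codes_by.get(pid, empty_codes)
        pdocs = docs_by.get(pid, empty_docs)
        death_date = _death_evidence(prow["death_date"], pdocs)
        censor_date = admin_censor
        if censor_at_last_contact and pid in last_contact:
            censor_date = min(censor_date, last_contact[pid])
        if death_date is not None:
            censor_date = min(censor_date, death_date)

        # death outcome: no competing event
        if death_date is not None:
            rows.append((pid, "death", (death_date - nafld).days, EVENT, False))
        else:
            rows.append((pid, "death", (censor_date - nafld).days, CENSORED, False))

        for defn in outcome_defs:
            evidence = _earliest_evidence(defn, pcodes, pdocs)
            if evidence is not None and (evidence - nafld).days <= PREVALENT_WINDOW_DAYS:
                rows.append((pid, defn.name, max((evidence - nafld).days, 0), EVENT, True))
            elif evidence is not None and (death_date is None or evidence <= death_date):
                rows.append((pid, defn.name, (evidence - nafld).days, EVENT, False))
            elif death_date is not None:
                rows.append((pid, defn.name, (death_date - nafld).days, COMPETING_DEATH, False))
            else:
                rows.append((pid, defn.name, (censor_date - nafld).days, CENSORED, False))
    out = pd.DataFrame(
        rows, columns=["patient_id", "outcome", "time_days", "event", "prevalent"]
    )
    out["time_days"] = out["time_days"].clip(lower=0)
    return out


# ---------------------------------------------------------------------------
# covariates


def build_covariates(
    bundle: EmrBundle,
    decisions: pd.DataFrame,
    assignment_mapping: dict,
    fib4_window_days: int = 365,
) -> pd.DataFrame:
    """Model covariates per eligible patient.

    Subtype indicators (reference = subtype 1, the largest), age at
    diagnosis (decades), female sex, race combined with ethnicity
    (Hispanic precedence, reference White), FIB-4 category indicators
    (reference low, separate 'missing').
    """
    elig = decisions[decisions["eligible"]]
    patients = bundle.patients.set_index("patient_id")
    labs_by = dict(iter(bundle.lab_results.groupby("patient_id", sort=False)))
    rows = []
    subtypes = sorted(set(assignment_mapping.values()))
    for dec in elig.itertuples():
        pid = dec.patient_id
        if pid not in assignment_mapping:
            continue
        prow = patients.loc[pid]
        nafld = _as_date(dec.nafld_date)
        age = (nafld - _as_date(prow["birth_date"])).days / 365.25
        race = prow["race"] if prow["race"] in ("White", "Black", "Asian") else "Other"
        if prow["ethnicity"] == "Hispanic":
            race = "Hispanic"  # ethnicity precedence
        labs = labs_by.get(pid)
        fib_inputs = {}
        if labs is not None:
            near = labs[
                (labs["value_num"].notna())
                & (abs((pd.to_datetime(labs["date"]) - pd.Timestamp(nafld)).dt.days) <= fib4_window_days)
            ]
            for test in ("AST", "ALT", "platelets"):
                sub = near[near["test_name"] == test]
                if not sub.empty:
                    closest = (pd.to_datetime(sub["date"]) - pd.Timestamp(nafld)).abs().idxmin()
                    fib_inputs[test] = float(sub.loc[closest, "value_num"])
        fib_cat = fib4_category(
            age, fib_inputs.get("AST"), fib_inputs.get("ALT"), fib_inputs.get("platelets")
        )
        row = {
            "patient_id": pid,
            "age_decades": age / 10.0,
            "female": int(prow["sex"] == "F"),
        }
        for s in subtypes:
            if s != 1:
                row[f"subtype_{s}"] = int(assignment_mapping[pid] == s)
        for cat in ("Black", "Asian", "Hispanic", "Other"):
            row[f"race_{cat.lower()}"] = int(race == cat)
        for cat in ("indeterminate", "high", "missing"):
            row[f"fib4_{cat}"] = int(fib_cat == cat)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def fit_outcome_models(
    outcome_table: pd.DataFrame,
    covariates: pd.DataFrame,
    univariate_cols: tuple = None,
) -> dict:
    """Cox (death) / Fine-Gray (others) fits per outcome.

    Prevalent rows are dropped; rows with zero follow-up get half a day
    so that the partial likelihood is defined.  Returns
    {outcome: HazardModelFit}.
    """
    fits = {}
    for outcome, sub in outcome_table.groupby("outcome"):
        sub = sub[~sub["prevalent"]].merge(
            covariates, left_on="patient_id", right_index=True, how="inner"
        )
        if sub.empty or (sub["event"] == EVENT).sum() == 0:
            continue
        cols = list(univariate_cols) if univariate_cols else [
            c for c in covariates.columns
        ]
        times = sub["time_days"].to_numpy(dtype=float)
        times[times <= 0] = 0.5
        X = sub[cols].to_numpy(dtype=float)
        keep = X.std(axis=0) > 0
        X, names = X[:, keep], [c for c, k in zip(cols, keep) if k]
        if outcome == "death":
            fits[outcome] = cox_ph(times, sub["event"] == EVENT, X, names)
        else:
            fits[outcome] = fine_gray(times, sub["event"].to_numpy(), X, names)
    return fits


# ---------------------------------------------------------------------------
# simulation helpers (parameter-recovery checks)


def simulate_two_arm_exponential(
    n: int, hr: float, baseline_hazard: float, censor_time: float, rng
) -> tuple:
    """Two equal arms with exponential event times, arm hazard ratio
    ``hr``, administrative censoring.  Returns (times, events, x)."""
    x = (np.arange(n) % 2).astype(float)
    rng.shuffle(x)
    rates = baseline_hazard * hr**x
    t = rng.exponential(1.0 / rates)
    events = t <= censor_time
    return np.minimum(t, censor_time), events, x


def simulate_fine_gray_latent(
    n: int, beta: float, p_cause1: float = 0.4, censor_max: float = 4.0, rng=None
) -> tuple:
    """Two-cause data from the Fine-Gray latent construction with true
    subdistribution log-HR ``beta`` for a binary covariate.

    Cause-1 subdistribution: F1(t; x) = 1 - (1 - p(1 - e^-t))^exp(x*beta);
    cause-2 times are unit exponential; censoring Uniform(0, censor_max).
    Returns (times, codes, x).
    """
    x = (np.arange(n) % 2).astype(float)
    rng.shuffle(x)
    ebx = np.exp(beta * x)
    p1 = 1.0 - (1.0 - p_cause1) ** ebx  # P(cause 1 | x), t -> inf
    cause1 = rng.random(n) < p1
    u = rng.random(n)
    # invert F1(t|cause 1) = u: t = -log(1 - (1 - (1 - u*p1)^(1/ebx)) / p)
    inner = 1.0 - (1.0 - u[cause1] * p1[cause1]) ** (1.0 / ebx[cause1])
    t1 = -np.log(1.0 - inner / p_cause1)
    t = np.empty(n)
    t[cause1] = t1
    t[~cause1] = rng.exponential(1.0, size=(~cause1).sum())
    c = rng.uniform(0, censor_max, size=n)
    observed = t <= c
    codes = np.where(observed, np.where(cause1, 1, 2), 0)
    return np.minimum(t, c), codes, x
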