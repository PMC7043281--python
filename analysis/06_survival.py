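"""Outcome analysis by subtype under competing risks.

Builds per-outcome time-to-event tables (incident cases only; death
competes), estimates the Kaplan-Meier curve for overall survival and
Aalen-Johansen cumulative incidence for the other outcomes, and fits
Cox (death) / Fine-Gray (non-death) models with subtype indicators
(reference subtype 1), age, sex, race/ethnicity, and FIB-4 category.
"""

import argparse
from pathlib import Path

import pandas as pd

from nafld_subtypes import io as bundle_io
from nafld_subtypes.survival import (
    build_covariates,
    build_outcome_table,
    cumulative_incidence,
    fit_outcome_models,
    kaplan_meier,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = bundle_io.read_bundle(args.out / "bundle")
    decisions = pd.read_csv(args.out / "decisions.csv", parse_dates=["nafld_date"])
    assign = pd.read_csv(args.out / "assignments.csv")
    mapping = dict(zip(assign["patient_id"], assign["subtype"]))

    table = build_outcome_table(bundle, decisions)
    table.to_csv(args.out / "outcome_table.csv", index=False)
    covariates = build_covariates(bundle, decisions, mapping)
    covariates.to_csv(args.out / "covariates.csv")

    death = table[table["outcome"] == "death"]
    kaplan_meier(death["time_days"], death["event"] == 1).to_csv(
        args.out / "km_death.csv", index=False
    )
    for outcome, sub in table.groupby("outcome"):
        if outcome == "death":
            continue
        sub = sub[~sub["prevalent"]]
        for code, curve in cumulative_incidence(
            sub["time_days"].to_numpy(), sub["event"].to_numpy()
        ).items():
            curve.to_csv(args.out / f"cif_{outcome}_type{code}.csv", index=False)

    for outcome, sub in table.groupby("outcome"):
        n_ev = int((sub["event"] == 1).sum() - sub["prevalent"].sum())
        print(f"{outcome}: {n_ev} incident events, {int(sub['prevalent'].sum())} prevalent excluded")

    fits = fit_outcome_models(table, covariates)
    frames = []
    for outcome, fit in fits.items():
        s = fit.summary.copy()
        s.insert(0, "outcome", outcome)
        s.insert(1, "model", fit.model)
        s["converged"] = fit.converged
        frames.append(s)
        sub5 = s[s["covariate"] == "subtype_5"]
        if not sub5.empty:
            r = sub5.iloc[0]
            print(
                f"{outcome} ({fit.model}): subtype 5 vs 1 HR {r.hr:.2f} "
                f"(95% CI {r.ci_lower:.2f}-{r.ci_upper:.2f}, p={r.p:.3g})"
            )
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(args.out / "hazard_models.csv", index=False)


if __name__ == "__main__":
    main()
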