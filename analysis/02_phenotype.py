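"""Apply the NAFLD electronic phenotype to the simulated bundle.

Reports how many patients meet the cohort definition (persistent ALT
elevation or liver-disease codes, no exclusions, positive steatosis
mention, diagnosis date inside 2013-01-01..2019-01-31) and why the rest
fail; writes per-patient decisions to results/decisions.csv.
"""

import argparse
from pathlib import Path

from nafld_subtypes import io as bundle_io
from nafld_subtypes.phenotype import PhenotypeRuleConfig, classify_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = bundle_io.read_bundle(args.out / "bundle")
    decisions = classify_cohort(bundle, PhenotypeRuleConfig())
    decisions.to_csv(args.out / "decisions.csv", index=False)

    n_elig = int(decisions["eligible"].sum())
    print(f"eligible: {n_elig}/{len(decisions)}")
    failures = decisions.loc[~decisions["eligible"], "failed_rules"].value_counts()
    for rules, count in failures.items():
        print(f"  ineligible ({count}): {rules}")


if __name__ == "__main__":
    main()
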