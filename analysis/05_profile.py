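"""Profile each subtype against all remaining patients.

Chi-squared on every binary feature, Benjamini-Hochberg FDR across all
tests, significance at q < 0.001.  Writes one profile CSV per subtype
and prints each subtype's most enriched features.
"""

import argparse
from pathlib import Path

import pandas as pd

from nafld_subtypes.cluster import ClusterAssignment
from nafld_subtypes.features import FeatureMatrix
from nafld_subtypes.stats import enriched_feature_sets, profile_subtypes


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fdr", type=float, default=0.001)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    dense = pd.read_csv(args.out / "features" / "features_dense.csv", index_col=0)
    assign = pd.read_csv(args.out / "assignments.csv").set_index("patient_id")
    matrix = FeatureMatrix(
        patient_ids=list(dense.index),
        feature_names=list(dense.columns),
        values=dense.to_numpy(),
    )
    assignment = ClusterAssignment(
        labels=assign.loc[dense.index, "subtype"].to_numpy(),
        k=int(assign["subtype"].max()),
        patient_ids=list(dense.index),
    )
    profiles = profile_subtypes(matrix, assignment, args.fdr)
    sets = enriched_feature_sets(profiles, args.fdr)
    for lab, frame in profiles.items():
        frame.to_csv(args.out / f"profile_subtype_{lab}.csv", index=False)
        enriched = frame[frame["feature"].isin(sets[lab])].head(5)
        desc = ", ".join(
            f"{r.feature} ({100 * r.prop_in:.0f}% vs {100 * r.prop_out:.0f}%)"
            for r in enriched.itertuples()
        )
        print(f"subtype {lab}: {len(sets[lab])} enriched features; top: {desc or 'none'}")


if __name__ == "__main__":
    main()
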