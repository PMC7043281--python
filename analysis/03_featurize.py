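"""Build the binary feature matrix for the eligible cohort.

Age bins, sex, race/ethnicity, phecode diagnoses (>= 0.1% prevalence),
CPT procedure groups, chronic medications (two orders >= 6 months
apart), abnormal labs and abnormal vitals; written dense (CSV) and
sparse (Matrix-Market) under results/features/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nafld_subtypes import io as bundle_io
from nafld_subtypes.features import build_feature_matrix


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = bundle_io.read_bundle(args.out / "bundle")
    decisions = pd.read_csv(args.out / "decisions.csv", parse_dates=["nafld_date"])
    matrix = build_feature_matrix(bundle, decisions)
    bundle_io.write_feature_matrix(matrix, args.out / "features")

    n, m = matrix.values.shape
    print(f"feature matrix: {n} patients x {m} binary features")
    print(matrix.provenance["domain"].value_counts().to_string())


if __name__ == "__main__":
    main()
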