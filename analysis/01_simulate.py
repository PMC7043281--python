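"""Generate the synthetic EMR cohort the analysis runs on.

Writes the multi-table bundle (patients, coded events, medication
orders, labs, vitals, free-text documents) plus the hidden truth table
(planted subtype and latent outcome times) under results/.
"""

import argparse
from pathlib import Path

from nafld_subtypes import io as bundle_io
from nafld_subtypes.pipeline import stage_seed
from nafld_subtypes.synthetic import default_cohort_config, generate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=500, help="cohort size")
    ap.add_argument("--seed", type=int, default=0, help="master seed")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = default_cohort_config(args.n, stage_seed(args.seed, "simulate"))
    bundle, truth, doc_truth = generate_cohort(config)
    out = args.out
    bundle_io.write_bundle(bundle, out / "bundle")
    truth.to_csv(out / "truth.csv", index=False)
    doc_truth.to_csv(out / "doc_truth.csv", index=False)

    sizes = truth["subtype"].value_counts().sort_index()
    print(f"simulated {len(bundle.patients)} patients into {out / 'bundle'}")
    print("planted subtype sizes:", dict(sizes))
    print(f"documents: {len(bundle.documents)}, code events: {len(bundle.code_events)}")


if __name__ == "__main__":
    main()
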