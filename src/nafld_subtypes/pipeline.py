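"""Pipeline orchestration: simulate -> phenotype -> featurize -> cluster
-> analyze -> survival -> validate, with per-stage manifests.

Every randomized stage derives its seed deterministically from the
master seed and the stage name, so a rerun with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as bundle_io
from .cluster import cut_tree, manhattan_distances, ward_linkage
from .features import build_feature_matrix
from .phenotype import PhenotypeRuleConfig, classify_cohort
from .stats import profile_subtypes
from .survival import (
    build_covariates,
    build_outcome_table,
    cumulative_incidence,
    fit_outcome_models,
    kaplan_meier,
)
from .synthetic import default_cohort_config, generate_cohort
from .validation import subsample_and_recluster

log = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "featurize", "cluster", "analyze", "survival", "validate")


@dataclass
class PipelineConfig:
    out_dir: str
    master_seed: int = 0
    n_patients: int = 500
    k: int = 5
    fdr_threshold: float = 0.001
    validation_repeats: int = 10
    validation_fraction: float = 0.9
    min_feature_prevalence: float = 0.001
    censor_at_last_contact: bool = False

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr threshold must lie in (0, 1)")
        if not 0.0 < self.validation_fraction <= 1.0:
            raise ValueError("validation fraction must lie in (0, 1]")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _manifest(stage: str, out: Path, seed: int, inputs: dict) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "inputs": {
            k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
            for k, v in inputs.items()
            if Path(v).is_file()
        },
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in dependency order; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate
    seed = stage_seed(config.master_seed, "simulate")
    cohort_cfg = default_cohort_config(config.n_patients, seed)
    bundle, truth, doc_truth = generate_cohort(cohort_cfg)
    bundle_dir = bundle_io.write_bundle(bundle, out / "bundle")
    truth.to_csv(out / "truth.csv", index=False)
    doc_truth.to_csv(out / "doc_truth.csv", index=False)
    _manifest("simulate", out, seed, {"patients": bundle_dir / "patients.csv"})
    log.info("simulate: %d patients", len(bundle.patients))

    # --- phenotype
    decisions = classify_cohort(bundle, PhenotypeRuleConfig())
    decisions.to_csv(out / "decisions.csv", index=False)
    _manifest("phenotype", out, 0, {"decisions": out / "decisions.csv"})
    log.info("phenotype: %d/%d eligible", int(decisions["eligible"].sum()), len(decisions))

    # --- featurize
    matrix = build_feature_matrix(
        bundle, decisions, min_prevalence=config.min_feature_prevalence
    )
    bundle_io.write_feature_matrix(matrix, out / "features")
    _manifest("featurize", out, 0, {"dense": out / "features" / "features_dense.csv"})
    log.info("featurize: %d x %d", *matrix.values.shape)

    # --- cluster
    dend = ward_linkage(manhattan_distances(matrix.values))
    assignment = cut_tree(dend, config.k, matrix.patient_ids)
    pd.DataFrame(dend.merges, columns=["left", "right", "height", "size"]).to_csv(
        out / "dendrogram.csv", index=False
    )
    pd.DataFrame(
        {"patient_id": assignment.patient_ids, "subtype": assignment.labels}
    ).to_csv(out / "assignments.csv", index=False)
    _manifest("cluster", out, 0, {"assignments": out / "assignments.csv"})

    # --- analyze
    profiles = profile_subtypes(matrix, assignment, config.fdr_threshold)
    for lab, frame in profiles.items():
        frame.to_csv(out / f"profile_subtype_{lab}.csv", index=False)
    _manifest("analyze", out, 0, {"profile_1": out / "profile_subtype_1.csv"})

    # --- survival
    outcome_table = build_outcome_table(
        bundle, decisions, censor_at_last_contact=config.censor_at_last_contact
    )
    outcome_table.to_csv(out / "outcome_table.csv", index=False)
    covariates = build_covariates(bundle, decisions, assignment.to_mapping())
    covariates.to_csv(out / "covariates.csv")
    death = outcome_table[(outcome_table["outcome"] == "death")]
    kaplan_meier(death["time_days"], death["event"] == 1).to_csv(
        out / "km_death.csv", index=False
    )
    for outcome, sub in outcome_table.groupby("outcome"):
        if outcome == "death":
            continue
        sub = sub[~sub["prevalent"]]
        for code, curve in cumulative_incidence(
            sub["time_days"].to_numpy(), sub["event"].to_numpy()
        ).items():
            curve.to_csv(out / f"cif_{outcome}_type{code}.csv", index=False)
    fits = fit_outcome_models(outcome_table, covariates)
    summaries = []
    for outcome, fit in fits.items():
        s = fit.summary.copy()
        s.insert(0, "outcome", outcome)
        s.insert(1, "model", fit.model)
        s["converged"] = fit.converged
        summaries.append(s)
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(out / "hazard_models.csv", index=False)
    _manifest("survival", out, 0, {"outcomes": out / "outcome_table.csv"})

    # --- validate
    seed = stage_seed(config.master_seed, "validate")
    report = subsample_and_recluster(
        matrix,
        fraction=config.validation_fraction,
        repeats=config.validation_repeats,
        k=config.k,
        seed=seed,
    )
    report.per_repeat.to_csv(out / "stability.csv", index=False)
    (out / "stability_summary.txt").write_text(report.summary() + "\n")
    _manifest("validate", out, seed, {"stability": out / "stability.csv"})
    return out
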