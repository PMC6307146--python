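"""End-to-end orchestration of the fingerprint discovery pipeline.

The three-cohort design mirrors the discovery/refinement/validation roles:
the discovery cohort supplies the GEE EWAS screen and the stage-1 elastic
net, the refinement cohort the stage-2 elastic net, the discovery cohort's
medication records the confounding filter, and the validation cohort an
out-of-sample AUC for the final re-weighted logistic model.  A single
top-level seed drives every stochastic step through stage-derived
sub-seeds, so a rerun with the same configuration reproduces every
artifact byte for byte (timestamps live only in the run report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as efio
from .ewas import run_ewas
from .preprocess import (DeltaSet, build_delta, filter_complete_cpgs,
                         residualize_technical)
from .selection import (FingerprintModel, cascade_select, evaluate_fingerprint,
                        fit_fingerprint, medication_filter)
from .simulate import MEDICATION_CLASSES

logger = logging.getLogger(__name__)

ROLES = ("discovery", "refinement", "validation")


@dataclass
class CohortData:
    """One cohort's inputs, already in memory."""

    meth_baseline: pd.DataFrame
    meth_followup: pd.DataFrame
    phenotypes: pd.DataFrame
    technical_baseline: pd.DataFrame
    technical_followup: pd.DataFrame

    @classmethod
    def from_dir(cls, path: str | Path) -> "CohortData":
        path = Path(path)
        return cls(
            meth_baseline=efio.read_methylation_matrix(
                path / "meth_baseline.tsv"),
            meth_followup=efio.read_methylation_matrix(
                path / "meth_followup.tsv"),
            phenotypes=efio.read_table(path / "phenotypes.tsv"),
            technical_baseline=efio.read_table(
                path / "technical_baseline.tsv").set_index("individual"),
            technical_followup=efio.read_table(
                path / "technical_followup.tsv").set_index("individual"),
        )

    def medication_usage(self, visit: str) -> pd.DataFrame:
        sub = self.phenotypes[self.phenotypes["visit"] == visit]
        return sub.set_index("individual")[list(MEDICATION_CLASSES)]


@dataclass
class PipelineConfig:
    """One plain-text document drives a whole run."""

    cohort_dirs: dict = field(default_factory=dict)   # role -> directory
    out_dir: str = "epifinger_out"
    fdr_screen: float = 0.15
    nominal_alpha: float = 0.05
    suggestive_alpha: float = 0.001
    med_alpha: float = 0.05
    enet_alpha: float = 0.5
    lambda_strategy: str = "1se"
    folds: int = 10
    seed: int = 0
    window_bp: int = 1_000_000
    working_correlation: str = "independence"

    def __post_init__(self) -> None:
        for name in ("fdr_screen", "nominal_alpha", "suggestive_alpha",
                     "med_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1); got {v}")
        roles = list(self.cohort_dirs)
        if len(set(roles)) != len(roles):
            raise ValueError("cohort roles must be pairwise distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Parameters that determine results (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d


@dataclass
class RunReport:
    funnel: dict                 # stage -> CpG count, non-increasing
    auc: dict                    # cohort role -> {auc, p, n, n_events}
    stage_dims: dict             # per-stage in/out dimensions
    config_hash: str
    seed: int
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def preprocess_cohort(cohort: CohortData) -> tuple[DeltaSet, dict]:
    """Completeness filter, per-visit residualization, ΔCpG construction."""
    b, f, report = filter_complete_cpgs(cohort.meth_baseline,
                                        cohort.meth_followup)
    rb = residualize_technical(b, cohort.technical_baseline)
    rf = residualize_technical(f, cohort.technical_followup)
    delta = build_delta(rb, rf, cohort.phenotypes)
    report["n_individuals"] = len(delta.individuals)
    return delta, report


def run_cohorts(
    cohorts: dict,
    config: PipelineConfig | None = None,
) -> tuple[RunReport, dict]:
    """Run the full pipeline on in-memory cohorts keyed by role.

    Returns the run report plus an artifact dict (EWAS table, selection
    results, medication records, fingerprint model, ROC results).
    """
    config = config or PipelineConfig()
    missing = [r for r in ROLES if r not in cohorts]
    if missing:
        raise ValueError(f"missing cohort roles: {missing}")
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage_dims: dict = {}

    deltas: dict[str, DeltaSet] = {}
    for role in ROLES:
        delta, rep = preprocess_cohort(cohorts[role])
        deltas[role] = delta
        stage_dims[f"preprocess_{role}"] = rep
        logger.info("%s: %d individuals x %d complete CpGs", role,
                    len(delta.individuals), len(delta.cpgs))

    ewas_table = run_ewas(deltas["discovery"],
                          working_correlation=config.working_correlation)
    survivors = ewas_table.loc[ewas_table["q"] < config.fdr_screen,
                               "cpg"].tolist()
    # the cascade and the final model need the CpGs in every cohort
    present_everywhere = set(deltas["discovery"].cpgs)
    for role in ("refinement", "validation"):
        present_everywhere &= set(deltas[role].cpgs)
    survivors = [c for c in survivors if c in present_everywhere]
    stage_dims["ewas"] = {"n_tested": int(len(ewas_table)),
                          "n_survivors": len(survivors)}
    if not survivors:
        raise RuntimeError("EWAS screen retained no CpGs at "
                           f"FDR < {config.fdr_screen}")

    final_set, stage1, stage2 = cascade_select(
        deltas["discovery"].wide, deltas["discovery"].outcome,
        deltas["refinement"].wide, deltas["refinement"].outcome,
        survivors, alpha=config.enet_alpha,
        lambda_strategy=config.lambda_strategy,
        seed=config.seed, folds=config.folds)

    disc = cohorts["discovery"]
    med_b = disc.medication_usage("baseline")
    med_f = disc.medication_usage("followup")
    retained, med_records = medication_filter(
        deltas["discovery"].wide, med_b, med_f, final_set,
        alpha=config.med_alpha)
    if not retained:
        raise RuntimeError("medication filter removed every candidate CpG")

    models: dict[str, FingerprintModel] = {}
    auc: dict[str, dict] = {}
    for role in ("discovery", "refinement"):
        model = fit_fingerprint(deltas[role].wide, deltas[role].outcome,
                                retained, training_cohort=role)
        models[role] = model
        roc = evaluate_fingerprint(model, deltas[role].wide,
                                   deltas[role].outcome)
        auc[role] = {"auc": roc.auc, "p": roc.p, "n": roc.n,
                     "n_events": roc.n_events, "in_sample": True}
    roc_val = evaluate_fingerprint(models["discovery"],
                                   deltas["validation"].wide,
                                   deltas["validation"].outcome)
    auc["validation"] = {"auc": roc_val.auc, "p": roc_val.p, "n": roc_val.n,
                        "n_events": roc_val.n_events, "in_sample": False}

    funnel = {
        "complete_cpgs": len(deltas["discovery"].cpgs),
        "ewas_survivors": len(survivors),
        "stage1_nonzero": len(stage1.selected),
        "stage2_nonzero": len(stage2.selected),
        "post_medication_filter": len(retained),
    }
    report = RunReport(
        funnel=funnel, auc=auc, stage_dims=stage_dims,
        config_hash=efio.config_hash(config.analysis_dict()),
        seed=config.seed,
        started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    artifacts = {
        "deltas": deltas,
        "ewas": ewas_table,
        "survivors": survivors,
        "stage1": stage1,
        "stage2": stage2,
        "medication_records": med_records,
        "fingerprint": models["discovery"],
        "models": models,
        "roc_validation": roc_val,
    }
    return report, artifacts


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-driven pipeline run: read cohort directories, write artifacts."""
    cohorts = {role: CohortData.from_dir(path)
               for role, path in config.cohort_dirs.items()}
    report, artifacts = run_cohorts(cohorts, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": report.config_hash}
    efio.write_table(artifacts["ewas"], out / "ewas.tsv", meta=meta)
    efio.write_fingerprint_model(artifacts["fingerprint"],
                                 out / "model.txt", meta=meta)
    roc = artifacts["roc_validation"]
    efio.write_table(pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}),
                     out / "roc_validation.tsv", meta=meta)
    med_frame = pd.DataFrame([dataclasses.asdict(r)
                              for r in artifacts["medication_records"]])
    efio.write_table(med_frame, out / "medication_tests.tsv", meta=meta)
    (out / "report.json").write_text(report.to_json())
    return report
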