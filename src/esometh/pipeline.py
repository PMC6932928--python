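"""End-to-end orchestration of the diagnostic and prognostic arms.

The diagnostic arm simulates (or loads) an eight-class discovery cohort,
splits it 2:1 into training and test partitions stratified by tissue class,
identifies tissue-specific markers on the training partition only, runs the
grouped-lasso stability selection, fits the final multinomial model on the
training partition, and reports confusion matrices and micro-average AUCs
for training, test and an independently simulated external validation
cohort. The prognostic arm runs the DMC -> adjusted-Cox -> lasso-Cox
stability -> risk-score chain for one histology.

A single pipeline seed fans out to per-stage child seeds (cohort noise,
partitioning, cross-validation, subsampling) so every stage is
independently reproducible and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .diagnostic import (
    DiagnosticModel,
    GroupedLassoConfig,
    fit_final_multinomial,
    stability_select,
)
from .diffmeth import moderated_t, select_dmc, tissue_specific_markers
from .evaluation import (
    confusion_summary,
    cox_table,
    km_logrank,
    micro_average_auc,
    risk_stratify,
    time_dependent_auc,
)
from .exceptions import ConfigurationError, ValidationError
from .prognostic import (
    build_risk_score,
    encode_clinical,
    independent_prognostic_filter,
    lasso_cox_stability,
)
from .simulate import ESOPHAGEAL_CLASSES, SimulationConfig, simulate_dataset

logger = logging.getLogger("esometh")


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the two arms, defaulting to the study's constants."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fdr_threshold: float = 0.05
    dmc_delta_threshold: float = 0.2
    diag: GroupedLassoConfig = field(default_factory=GroupedLassoConfig)
    prog_n_reps: int = 100
    prog_subsample_fraction: float = 0.75
    prog_n_folds: int = 5
    prog_freq_threshold: int = 30
    cohort_train_fraction: float = 2.0 / 3.0
    validation_n_per_class: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        diag = GroupedLassoConfig(**raw.pop("diag", {}))
        return cls(simulation=sim, diag=diag, **raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n).astype(np.int64)
    return [int(s & 0x7FFFFFFF) for s in state]


def _check_disjoint(*cohorts: pd.Index) -> None:
    for i in range(len(cohorts)):
        for j in range(i + 1, len(cohorts)):
            shared = cohorts[i].intersection(cohorts[j])
            if len(shared) > 0:
                raise ValidationError(
                    f"cohort leakage: shared sample ids {shared[:5].tolist()}"
                )


def _evaluate_cohort(model: DiagnosticModel, X: pd.DataFrame, y) -> dict:
    pred = model.predict(X)
    cs = confusion_summary(y, pred, labels=model.classes)
    roc = micro_average_auc(y, model.predict_proba(X))
    return {
        "confusion": cs,
        "accuracy_pct": cs.overall_accuracy,
        "accuracy_ci_pct": cs.ci,
        "per_class_accuracy_pct": cs.per_class_accuracy.to_dict(),
        "micro_auc": roc.auc,
        "n": cs.n,
    }


def run_diagnostic_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Simulate, select markers, fit and evaluate the diagnostic classifier."""
    seeds = _child_seeds(config.seed, 4)
    sim = config.simulation

    matrix, sheet, truth = simulate_dataset(sim, cohort_seed=seeds[0])
    val_counts = {c: config.validation_n_per_class for c in ESOPHAGEAL_CLASSES}
    vmatrix, vsheet, _ = simulate_dataset(
        sim, cohort_seed=seeds[1], n_per_class=val_counts, sample_prefix="V"
    )

    # stratified 2:1 train/test split of the discovery cohort
    rng = np.random.default_rng(seeds[2])
    cohort = pd.Series("train", index=sheet.index)
    for cls, members in sheet.groupby("tissue_class").groups.items():
        members = list(members)
        n_test = int(round((1.0 - config.cohort_train_fraction) * len(members)))
        test_ids = rng.choice(members, size=n_test, replace=False)
        cohort.loc[test_ids] = "test"
    sheet = sheet.assign(cohort=cohort)
    vsheet = vsheet.assign(cohort="validation")
    train_ids = sheet.index[sheet["cohort"] == "train"]
    test_ids = sheet.index[sheet["cohort"] == "test"]
    _check_disjoint(train_ids, test_ids, vsheet.index)

    logger.info("marker discovery on %d training samples", len(train_ids))
    markers = tissue_specific_markers(
        matrix[train_ids], sheet.loc[train_ids], config.fdr_threshold
    )
    marker_ids = [g for g in matrix.index if g in markers.union]
    if not marker_ids:
        raise ValidationError("no tissue-specific markers found")

    eso_train = [
        s for s in train_ids if sheet.loc[s, "tissue_class"] in ESOPHAGEAL_CLASSES
    ]
    eso_test = [
        s for s in test_ids if sheet.loc[s, "tissue_class"] in ESOPHAGEAL_CLASSES
    ]
    X_train = matrix.loc[marker_ids, eso_train].T
    y_train = sheet.loc[eso_train, "tissue_class"].to_numpy()

    diag_cfg = dataclasses.replace(config.diag, seed=seeds[3])
    logger.info(
        "stability selection over %d markers, %d partitions",
        len(marker_ids),
        diag_cfg.n_partitions,
    )
    stability = stability_select(X_train, y_train, diag_cfg)
    selected = stability.selected
    logger.info("selected %d CpGs at frequency >= %d", len(selected), diag_cfg.freq_threshold)

    model = fit_final_multinomial(X_train[selected], y_train)

    X_test = matrix.loc[selected, eso_test].T
    y_test = sheet.loc[eso_test, "tissue_class"].to_numpy()
    X_val = vmatrix.loc[selected].T
    y_val = vsheet["tissue_class"].to_numpy()

    report = {
        "seed": config.seed,
        "child_seeds": seeds,
        "thresholds": {
            "fdr": config.fdr_threshold,
            "freq_threshold": diag_cfg.freq_threshold,
            "n_partitions": diag_cfg.n_partitions,
            "n_folds": diag_cfg.n_folds,
        },
        "n_markers": len(marker_ids),
        "markers_per_class": {c: len(v) for c, v in markers.per_class.items()},
        "selected_cpgs": selected,
        "frequencies": stability.frequencies.to_dict(),
        "truth": truth,
        "model": model,
        "train": _evaluate_cohort(model, X_train[selected], y_train),
        "test": _evaluate_cohort(model, X_test, y_test),
        "validation": _evaluate_cohort(model, X_val, y_val),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.to_json(outdir / "diagnostic_model.json")
        stability.to_frame().to_csv(outdir / "stability_frequencies.tsv", sep="\t")
        markers.to_frame().to_csv(outdir / "tissue_specific_markers.tsv", sep="\t", index=False)
        eio.write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
        with open(outdir / "diagnostic_report.json", "w") as fh:
            json.dump(_jsonable_report(report), fh, indent=2)
    return report


def _jsonable_report(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if k in ("truth", "model"):
            continue
        if isinstance(v, dict):
            out[k] = {
                kk: vv
                for kk, vv in v.items()
                if isinstance(vv, (int, float, str, list, tuple, dict))
            }
        elif isinstance(v, (int, float, str, list, tuple)):
            out[k] = v
    return out


def run_prognostic_pipeline(
    config: PipelineConfig,
    histology: str,
    *,
    n_tumor: int = 200,
    n_normal: int = 50,
    outdir=None,
) -> dict:
    """DMC screen, adjusted-Cox filter, lasso-Cox stability and risk model."""
    if histology not in ("EAC", "ESCC"):
        raise ConfigurationError("histology must be 'EAC' or 'ESCC'")
    seeds = _child_seeds(config.seed ^ (0x5A5A if histology == "ESCC" else 0), 3)
    sim = config.simulation
    counts = {histology: n_tumor, "NSE": n_normal}
    matrix, sheet, truth = simulate_dataset(
        sim, cohort_seed=seeds[0], n_per_class=counts, sample_prefix=f"{histology[0]}"
    )
    tumor_ids = sheet.index[sheet["tissue_class"] == histology].tolist()
    normal_ids = sheet.index[sheet["tissue_class"] == "NSE"].tolist()
    if sheet.loc[tumor_ids, "os_event"].sum() < 2:
        raise ValidationError("fewer than two events among tumor samples")

    fit = moderated_t(matrix, tumor_ids, normal_ids)
    dmcs = select_dmc(fit, config.dmc_delta_threshold, config.fdr_threshold)
    logger.info("%s: %d DMCs", histology, len(dmcs))

    tumor_sheet = sheet.loc[tumor_ids]
    candidates, screen_table = independent_prognostic_filter(
        dmcs, matrix, tumor_sheet, return_table=True
    )
    logger.info("%s: %d adjusted-Cox candidates", histology, len(candidates))

    X_cand = matrix.loc[candidates, tumor_ids].T
    stability = lasso_cox_stability(
        X_cand,
        tumor_sheet["os_time"].to_numpy(dtype=float),
        tumor_sheet["os_event"].to_numpy(dtype=int),
        n_reps=config.prog_n_reps,
        subsample_fraction=config.prog_subsample_fraction,
        n_folds=config.prog_n_folds,
        freq_threshold=config.prog_freq_threshold,
        seed=seeds[1],
    )
    selected = stability.selected
    logger.info("%s: %d selected CpGs", histology, len(selected))

    model = build_risk_score(selected, matrix[tumor_ids], tumor_sheet)
    groups = model.groups
    times = tumor_sheet.loc[groups.index, "os_time"].to_numpy(dtype=float)
    events = tumor_sheet.loc[groups.index, "os_event"].to_numpy(dtype=int)

    survival = km_logrank(times, events, groups)
    clinical = encode_clinical(tumor_sheet.loc[groups.index])
    factors = clinical.rename(columns={"stage_advanced": "stage_III_IV"})
    factors["classifier_high_risk"] = (groups == "high").astype(float)
    complete = factors.notna().all(axis=1).to_numpy()
    ct = cox_table(factors.loc[complete], times[complete], events[complete])
    horizon = float(np.median(times))
    td_auc = time_dependent_auc(model.risk_scores.to_numpy(), times, events, horizon)
    strat = risk_stratify(groups, tumor_sheet.loc[groups.index])

    report = {
        "histology": histology,
        "seed": config.seed,
        "n_tumor": len(tumor_ids),
        "n_events": int(events.sum()),
        "n_dmcs": len(dmcs),
        "n_candidates": len(candidates),
        "selected_cpgs": selected,
        "frequencies": stability.frequencies.to_dict(),
        "truth": truth,
        "model": model,
        "screen_table": screen_table,
        "logrank_p": survival.p,
        "cox_table": ct,
        "time_dependent_auc": td_auc,
        "td_auc_horizon": horizon,
        "risk_stratification": strat,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.to_json(outdir / f"prognostic_model_{histology}.json")
        pd.DataFrame(
            {"risk_score": model.risk_scores, "risk_group": groups}
        ).to_csv(outdir / f"risk_scores_{histology}.tsv", sep="\t")
        ct.to_csv(outdir / f"cox_table_{histology}.tsv", sep="\t")
    return report


def overlap_report(report_a: dict, report_b: dict) -> dict:
    """Intersection of the selected prognostic panels of two histologies."""
    a = set(report_a["selected_cpgs"])
    b = set(report_b["selected_cpgs"])
    return {
        report_a["histology"]: sorted(a),
        report_b["histology"]: sorted(b),
        "overlap": sorted(a & b),
        "n_overlap": len(a & b),
    }
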