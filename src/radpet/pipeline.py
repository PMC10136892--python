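"""End-to-end orchestration: simulate -> segment -> extract -> filter ->
select -> model -> survive, for both analysis targets (response at second
follow-up; overall progression), from a single configuration.

The pipeline is deterministic for a fixed seed: the synthetic generator fans
the global seed out to per-patient substreams, and the split and Boruta
stages take their seeds from the analysis configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidCategoryError, NoTumorFoundError
from .features import DEFAULT_BIN_COUNT, DEFAULT_DISTANCES, extract_patient
from .grids import dice
from .reliability import DEFAULT_CCC_CUTOFF, reliability_filter
from .response import evaluate_signature
from .segmentation import liver_reference_stats, percist_threshold, segment_lesions
from .selection import (BorutaSelector, UnitIntervalScaler, correlation_prune,
                        split_cohort)
from .survival import DichotomyResult, dichotomized_pfs_analysis
from .synthetic import (REFERENCE_RECIST_COUNTS, REFERENCE_TPS_COUNTS,
                        TPS_LEVELS, SyntheticConfig, SyntheticPatient,
                        generate_cohort)

logger = logging.getLogger("radpet")

TARGETS = ("response", "progression")

# outcome-table column holding each target's label, and the adverse level
_TARGET_COLUMNS = {"response": "responder", "progression": "overall_progression"}


def classify_response(recist_category: str) -> bool:
    """RECIST 1.1 response dichotomy: CR/PR/SD are responders, PD is not."""
    if recist_category in ("CR", "PR", "SD"):
        return True
    if recist_category == "PD":
        return False
    raise InvalidCategoryError(f"unknown RECIST category {recist_category!r}")


def responder_counts(category_counts: dict[str, int]) -> tuple[int, int]:
    """(responders, non-responders) implied by per-category patient counts."""
    responders = sum(n for c, n in category_counts.items() if classify_response(c))
    non_responders = sum(n for c, n in category_counts.items()
                         if not classify_response(c))
    return responders, non_responders


def group_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in counts.items()}


@dataclass
class AnalysisConfig:
    """Knobs of the statistical stages (the image stages live in
    SyntheticConfig)."""

    ratio: float = 0.7
    ccc_cutoff: float = DEFAULT_CCC_CUTOFF
    bin_count: int = DEFAULT_BIN_COUNT
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    n_trees: int = 500
    max_iter: int = 100
    alpha: float = 0.01
    r_max: float = 0.8
    min_voxels: int = 2
    split_seed: int | None = None
    selection_seed: int | None = None


def _target_labels(cohort: pd.DataFrame, target: str) -> pd.Series:
    """Binary adverse-outcome labels (1 = worse) indexed by patient."""
    col = _TARGET_COLUMNS[target]
    values = cohort.set_index("patient_id")[col]
    return (~values if target == "response" else values).astype(int)


def extract_cohort_features(patients: list[SyntheticPatient],
                            analysis: AnalysisConfig,
                            ) -> tuple[dict[str, pd.DataFrame], list[dict], list[str]]:
    """Segment every phantom and extract both readers' feature tables.

    The PERCIST segmentation (liver excluded, small components dropped)
    defines the FDG-positive volume; each reader's mask is their manual
    adjustment of it — the intersection of the segmentation with the
    phantom's reader-specific rim edits. Patients whose PET shows no
    FDG-positive tumor are excluded with a log entry.
    """
    rows: dict[str, list[dict]] = {"R1": [], "R2": []}
    seg_records: list[dict] = []
    excluded: list[str] = []
    for patient in patients:
        stats = liver_reference_stats(patient.pet, patient.liver_mask)
        threshold = percist_threshold(stats)
        try:
            seg = segment_lesions(patient.pet, threshold,
                                  exclusion_masks=[patient.liver_mask],
                                  min_voxels=analysis.min_voxels)
        except NoTumorFoundError:
            logger.warning("patient %s excluded: no tumor at threshold %.3f",
                           patient.patient_id, threshold)
            excluded.append(patient.patient_id)
            continue
        masks = {"R1": patient.tumor_mask_reader1,
                 "R2": patient.tumor_mask_reader2}
        for reader, manual in masks.items():
            mask = dataclasses.replace(
                manual, data=manual.data & seg.tumor_mask.data,
                reader=reader, role="tumor")
            pet_f, ct_f = extract_patient(patient.pet, patient.ct, mask,
                                          reader_id=reader,
                                          bin_count=analysis.bin_count,
                                          distances=analysis.distances)
            rows[reader].append({"patient_id": patient.patient_id,
                                 **pet_f, **ct_f})
        seg_records.append({
            "patient_id": patient.patient_id,
            "threshold_suv": seg.threshold_suv,
            "n_components": seg.n_components,
            "total_mtv_ml": seg.total_mtv_ml,
            "liver_mean_suv": stats.mean_suv,
            "liver_sd_suv": stats.sd_suv,
            "reader_dice": dice(patient.tumor_mask_reader1,
                                patient.tumor_mask_reader2),
        })
    tables = {r: pd.DataFrame(rows[r]).set_index("patient_id")
              for r in ("R1", "R2")}
    return tables, seg_records, excluded


def _analyze_target(target: str, merged: pd.DataFrame, cohort: pd.DataFrame,
                    analysis: AnalysisConfig, seed: int) -> dict:
    labels = _target_labels(cohort, target)
    split = split_cohort(cohort, ratio=analysis.ratio,
                         seed=analysis.split_seed if analysis.split_seed is not None else seed,
                         stratify_by=_TARGET_COLUMNS[target])
    X_train = merged.loc[split.train_ids]
    X_test = merged.loc[split.test_ids]
    y_train = labels.loc[split.train_ids].to_numpy()
    y_test = labels.loc[split.test_ids].to_numpy()

    scaler = UnitIntervalScaler().fit(X_train)
    Xn_train = scaler.transform(X_train)
    Xn_test = scaler.transform(X_test)
    Xn_all = scaler.transform(merged)

    selector = BorutaSelector(
        n_trees=analysis.n_trees, max_iter=analysis.max_iter,
        alpha=analysis.alpha,
        random_state=(analysis.selection_seed
                      if analysis.selection_seed is not None else seed),
    ).fit(Xn_train, y_train)
    boruta = selector.result()

    result: dict = {
        "target": target,
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "n_features_in": int(merged.shape[1]),
        "n_features_normalized": int(Xn_train.shape[1]),
        "boruta": {
            "n_iter": boruta.n_iter,
            "n_confirmed": len(boruta.confirmed),
            "confirmed": boruta.confirmed,
            "params": boruta.params,
        },
    }
    if not boruta.confirmed:
        result["signature"] = []
        result["note"] = "Boruta confirmed no features for this target"
        return result

    signature = correlation_prune(Xn_train, boruta.confirmed,
                                  boruta.median_importance, analysis.r_max)
    result["signature"] = signature
    result["models"] = evaluate_signature(Xn_train, y_train, Xn_test, y_test,
                                          signature)

    survival_runs = []
    for feat_report in result["models"]["per_feature"]:
        feat = feat_report["feature"]
        thr = feat_report["youden_threshold"]
        exposure = "le" if feat_report["high_risk_side"] == "above" else "gt"
        for subgroup in (None, *TPS_LEVELS):
            try:
                run = dichotomized_pfs_analysis(
                    cohort, Xn_all[feat], thr, exposure_side=exposure,
                    subgroup=subgroup)
                survival_runs.append(_dichotomy_record(feat, run))
            except Exception as exc:  # degenerate subgroup splits etc.
                survival_runs.append({"feature": feat, "subgroup": subgroup,
                                      "skipped": str(exc)})
    result["survival"] = survival_runs
    return result


def _dichotomy_record(feature: str, run: DichotomyResult) -> dict:
    return {
        "feature": feature,
        "subgroup": run.subgroup,
        "threshold": run.threshold,
        "exposure_side": run.exposure_side,
        "n_exposed": run.n_exposed,
        "n_other": run.n_other,
        "logrank_chi2": run.chi2,
        "logrank_p": run.p_logrank,
        "hr": run.cox.hr,
        "hr_ci": [run.cox.ci_low, run.cox.ci_high],
        "cox_p": run.cox.p,
        "cox_converged": run.cox.converged,
    }


def run_pipeline(config: SyntheticConfig,
                 analysis: AnalysisConfig | None = None,
                 outdir: str | Path | None = None,
                 targets: tuple[str, ...] = TARGETS) -> dict:
    """Run the whole analysis on a freshly simulated cohort.

    Returns the machine-readable run report; when ``outdir`` is given the
    report, the cohort table, both readers' feature tables and the CCC report
    are persisted there, along with the resolved configuration.
    """
    analysis = analysis or AnalysisConfig()
    for t in targets:
        if t not in TARGETS:
            raise ValueError(f"unknown target {t!r}")

    logger.info("simulating %d phantoms", config.n_patients)
    patients, cohort = generate_cohort(config)
    tables, seg_records, excluded = extract_cohort_features(patients, analysis)
    cohort = cohort[~cohort["patient_id"].isin(excluded)].reset_index(drop=True)

    ccc_report = reliability_filter(tables["R1"], tables["R2"],
                                    cutoff=analysis.ccc_cutoff)

    report: dict = {
        "schema_version": 1,
        "software_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "analysis": asdict(analysis),
        "n_patients": int(len(cohort)),
        "excluded_patients": excluded,
        "segmentation": seg_records,
        "reliability": {
            "n_features_in": int(ccc_report.ccc.size),
            "n_kept": len(ccc_report.kept),
            "cutoff": analysis.ccc_cutoff,
        },
        "targets": {},
    }
    for target in targets:
        logger.info("analyzing target %s", target)
        report["targets"][target] = _analyze_target(
            target, ccc_report.merged, cohort, analysis, config.seed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_text(outdir / "config.txt")
        cohort.to_csv(outdir / "cohort.csv", index=False)
        tables["R1"].to_csv(outdir / "features_r1.csv")
        tables["R2"].to_csv(outdir / "features_r2.csv")
        ccc_report.to_frame().to_csv(outdir / "ccc_report.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
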