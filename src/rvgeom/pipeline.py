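"""Run orchestration: comparative and predictive analyses with reproducible
JSON reports.

A report is a plain, JSON-serialisable dict: config echo, package version,
per-stage row counts, every warning any stage emitted, and the result tables.
Serialisation is canonical (sorted keys), so identical config + data yield a
byte-identical report body.  All randomness flows from the single top-level
seed in the config; stage seeds are derived deterministically from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .classify import build_patient_profiles, loo_classify, match_distance_ratio, model_labels
from .stats import (
    fit_progression_logistic,
    flsd_posthoc,
    one_way_anova,
    summarize_groups,
)
from .types import GEOMETRY_FEATURES, GRADES, VISITS

logger = logging.getLogger("rvgeom")

#: Features compared across screening visits: only resolution-independent
#: quantities (angles and the junction exponent); absolute widths are
#: excluded because camera systems, and hence pixel scales, can change
#: between visits.
CROSS_VISIT_FEATURES = ["theta1", "theta2", "chi"]

#: Baseline features screened for progression odds ratios.
PROGRESSION_FEATURES = ["d0", "d1", "d2", "theta1", "theta2", "chi"]


@dataclass
class RunConfig:
    alpha: float = 0.05
    strata: tuple[str, ...] = ("all", "arteriole", "venule")
    threshold: float = 0.5
    seed: int = 0
    features_path: str = ""
    patients_path: str = ""
    out_dir: str = ""
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _base_report(config: RunConfig, kind: str) -> dict:
    return {
        "kind": kind,
        "config": asdict(config),
        "version": __version__,
        "counts": {},
        "warnings": [],
        "tables": {},
    }


def _grade_groups(merged: pd.DataFrame, feature: str) -> dict[str, np.ndarray]:
    groups = {}
    for g in GRADES:
        vals = merged.loc[merged["grade"] == g, feature].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            groups[g] = vals
    return groups


def run_comparative(
    features: pd.DataFrame, patients: pd.DataFrame, config: RunConfig
) -> dict:
    """Grade-wise summaries with ANOVA p-values and FLSD subset letters,
    for the pooled data and the arteriolar/venular strata."""
    missing = set(features["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise ValueError(f"patients without grade labels: {sorted(missing)}")
    report = _base_report(config, "comparative")
    report["counts"]["bifurcations_in"] = int(len(features))
    merged = features.merge(
        patients[["patient_id", "grade"]], on="patient_id", how="left"
    )

    for stratum in config.strata:
        sub = merged if stratum == "all" else merged[merged["vessel_type"] == stratum]
        if sub.empty:
            report["warnings"].append(f"stratum {stratum!r} empty; table omitted")
            continue
        table_rows = []
        for feature in GEOMETRY_FEATURES:
            groups = _grade_groups(sub, feature)
            if len(groups) < 2:
                report["warnings"].append(
                    f"{stratum}/{feature}: fewer than two grades with data"
                )
                continue
            anova = one_way_anova(groups)
            posthoc = flsd_posthoc(groups, anova, alpha=config.alpha)
            for g in groups:
                table_rows.append({
                    "feature": feature, "grade": g,
                    "mean": round(anova.group_means[g], 6),
                    "sd": round(anova.group_sds[g], 6),
                    "n": anova.group_ns[g],
                    "n_missing": int(sub.loc[sub["grade"] == g, feature].isna().sum()),
                    "anova_p": round(anova.p, 6),
                    "anova_F": round(anova.F, 6),
                    "significant": bool(anova.p <= config.alpha),
                    "letters": posthoc.letters[g],
                })
        report["tables"][stratum] = table_rows
        report["counts"][f"rows_{stratum}"] = int(len(sub))

    n_chi_missing = int(merged["chi"].isna().sum())
    report["counts"]["chi_undefined"] = n_chi_missing
    if n_chi_missing:
        report["warnings"].append(
            f"{n_chi_missing} bifurcation(s) with undefined junction exponent "
            "excluded from chi means"
        )
    return report


def run_predictive(
    features: pd.DataFrame, patients: pd.DataFrame, config: RunConfig
) -> dict:
    """Visit comparisons (angles and junction exponent only) and baseline
    progression odds-ratio table, pooled and per vessel type."""
    if "visit" not in features.columns:
        raise ValueError("predictive analysis needs a 'visit' column")
    for arm in (True, False):
        n = patients[patients["progressor"] == arm]["patient_id"].nunique()
        if n < 2:
            raise ValueError(f"need >= 2 patients per arm, got {n} for progressor={arm}")
    report = _base_report(config, "predictive")
    report["counts"]["bifurcations_in"] = int(len(features))
    merged = features.merge(
        patients[["patient_id", "progressor"]], on="patient_id", how="left"
    )

    # cross-visit comparisons for the progressors arm (widths excluded: pixel
    # scales are not comparable across visits)
    visit_tables: dict[str, list] = {}
    prog = merged[merged["progressor"] == True]  # noqa: E712
    for stratum in config.strata:
        sub = prog if stratum == "all" else prog[prog["vessel_type"] == stratum]
        if sub.empty:
            report["warnings"].append(f"visit stratum {stratum!r} empty")
            continue
        feats = CROSS_VISIT_FEATURES if stratum == "all" else ["theta1", "theta2"]
        rows = []
        for feature in feats:
            groups = {}
            for v in VISITS:
                vals = sub.loc[sub["visit"] == v, feature].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    groups[v] = vals
            if len(groups) < 2:
                continue
            anova = one_way_anova(groups)
            for v in groups:
                rows.append({
                    "feature": feature, "visit": v,
                    "mean": round(anova.group_means[v], 6),
                    "sd": round(anova.group_sds[v], 6),
                    "n": anova.group_ns[v],
                    "anova_p": round(anova.p, 6),
                })
        visit_tables[stratum] = rows
    report["tables"]["visit_comparison"] = visit_tables

    # baseline logistic odds ratios (Table-6 shape)
    baseline = features[features["visit"] == "baseline"]
    or_rows = []
    for stratum in config.strata:
        for feature in PROGRESSION_FEATURES:
            fit = fit_progression_logistic(baseline, patients, feature, stratum=stratum)
            if fit.penalized:
                report["warnings"].append(
                    f"progression fit {stratum}/{feature}: separation, "
                    "ridge-penalized estimate"
                )
            or_rows.append({
                "stratum": stratum, "feature": feature,
                "coefficient": round(fit.coefficient, 6),
                "odds_ratio": round(fit.odds_ratio, 6),
                "ci95_low": round(fit.ci95_low, 6),
                "ci95_high": round(fit.ci95_high, 6),
                "p": round(fit.p, 6),
                "n": fit.n,
                "penalized": fit.penalized,
            })
    report["tables"]["progression_odds_ratios"] = or_rows
    report["counts"]["baseline_rows"] = int(len(baseline))
    return report


def run_classification(
    features: pd.DataFrame,
    patients: pd.DataFrame,
    config: RunConfig,
    model_id: str = "one",
) -> dict:
    """Distance-ratio matching + patient profiles + LOO logistic model."""
    report = _base_report(config, f"classification-model-{model_id}")
    report["counts"]["bifurcations_in"] = int(len(features))

    match = match_distance_ratio(features)
    report["counts"]["bifurcations_kept"] = int(len(match.kept))
    report["counts"]["bifurcations_discarded"] = int(len(match.discarded))
    assert (report["counts"]["bifurcations_kept"]
            + report["counts"]["bifurcations_discarded"]
            == report["counts"]["bifurcations_in"])
    report["reference_patient"] = match.reference_id
    report["reference_mean_distance_ratio"] = round(match.reference_mean, 6)
    for pid in match.unmatchable:
        report["warnings"].append(f"patient {pid} unmatchable on distance ratio")

    profiles = build_patient_profiles(match)
    labels = model_labels(patients, model_id)
    extra = None
    if model_id == "two":
        nodr = patients.loc[patients["grade"] == "NoDR", "patient_id"].astype(str)
        extra = profiles[profiles["patient_id"].isin(nodr)]
    result = loo_classify(
        profiles, labels, model_id=model_id,
        threshold=config.threshold, extra_negatives=extra,
    )
    report["warnings"].extend(result.warnings)
    report["counts"]["patients"] = int(len(labels))
    report["counts"]["excluded_folds"] = result.n_excluded_folds
    report["tables"]["classification"] = {
        "model_id": result.model_id,
        "predictors": result.predictors,
        "threshold": result.threshold,
        "sensitivity": round(result.sensitivity, 4),
        "specificity": round(result.specificity, 4),
        "overall_specificity": (
            round(result.overall_specificity, 4)
            if result.overall_specificity is not None else None
        ),
        "predictions": [
            {"patient_id": p.patient_id, "true_class": p.true_class,
             "predicted_class": p.predicted_class,
             "probability": round(p.predicted_probability, 6)}
            for p in result.predictions
        ],
        "fold_coefficients": {
            k: [round(b, 8) for b in v]
            for k, v in result.fold_coefficients.items()
        },
    }
    return report


def serialize_report(report: dict) -> str:
    """Canonical JSON (sorted keys, fixed separators) for byte-stable output."""
    return json.dumps(report, sort_keys=True, indent=1)
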