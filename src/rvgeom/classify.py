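"""Patient-level grade assessment: ONH distance-ratio matching followed by
leave-one-out cross-validated logistic models.

Bifurcation geometry varies systematically with distance from the optic nerve
head, and the spatial spread of marked bifurcations can differ between
patients (image clarity tends to push markings closer to the disc).  Before
classification the per-patient bifurcation sets are therefore trimmed so that
every patient's mean ONH distance ratio is just below that of the patient
with the lowest mean ("the reference"), making the sets comparable.

Two binary models follow, each on patient-level feature means:

- model "one" separates no-retinopathy patients from any retinopathy
  (minimal/severe/proliferative merged), predictors mean parent diameter
  (d0) and mean smaller-child deflection angle (theta2);
- model "two" separates proliferative from non-proliferative retinopathy
  among the retinopathy cases, predictor mean parent diameter only, and can
  additionally score held-out no-retinopathy patients as extra negatives for
  an overall specificity.

Both are evaluated with leave-one-out cross-validation at a 0.5 probability
threshold (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logistic import fit_logistic, predict_proba
from .types import GRADES

MODEL_PREDICTORS = {
    "one": ["mean_parent_diameter", "mean_smaller_child_deflection"],
    "two": ["mean_parent_diameter"],
}


@dataclass
class MatchResult:
    kept: pd.DataFrame
    discarded: pd.DataFrame
    reference_id: str
    reference_mean: float
    unmatchable: list[str]
    per_patient: pd.DataFrame  # patient_id, n_kept, n_discarded, mean_ratio


@dataclass
class LooPrediction:
    patient_id: str
    true_class: int
    predicted_class: int
    predicted_probability: float


@dataclass
class ClassificationReport:
    model_id: str
    sensitivity: float  # percent
    specificity: float  # percent
    predictions: list[LooPrediction]
    fold_coefficients: dict[str, list[float]]
    predictors: list[str]
    threshold: float
    warnings: list[str] = field(default_factory=list)
    overall_specificity: float | None = None  # model two with extra negatives
    n_excluded_folds: int = 0


# ---------------------------------------------------------------------------
# distance-ratio matching
# ---------------------------------------------------------------------------

def match_distance_ratio(table: pd.DataFrame) -> MatchResult:
    """Trim per-patient bifurcation sets to equalise mean ONH distance ratios.

    The patient with the lowest mean distance ratio is the untrimmed
    reference.  For every other patient the highest-ratio bifurcation is
    removed repeatedly until the patient's mean is strictly below the
    reference mean ("just lower": restoring the last removal would leave the
    mean >= reference).  Ties among removal candidates are broken by removing
    the later-indexed row.  A patient trimmed down to a single bifurcation
    while still >= reference keeps that one row and is flagged unmatchable.
    """
    if table.empty:
        raise ValueError("empty feature table")
    if table["distance_ratio"].isna().any() or \
            not np.isfinite(table["distance_ratio"]).all():
        raise ValueError("every bifurcation needs a finite distance_ratio")

    means = table.groupby("patient_id", observed=True)["distance_ratio"].mean()
    ref_mean = float(means.min())
    # ties on the minimum broken by patient_id order
    reference_id = str(sorted(means[means == means.min()].index)[0])

    kept_parts: list[pd.DataFrame] = []
    discarded_parts: list[pd.DataFrame] = []
    unmatchable: list[str] = []
    summary = []
    for pid, sub in table.groupby("patient_id", observed=True, sort=False):
        if pid == reference_id:
            kept, n_disc = sub, 0
        else:
            # remove from the top: sort ascending by (ratio, row position) so
            # the tail is the current removal candidate — the later-indexed
            # row among equal ratios sorts last and is removed first
            order = sub.reset_index(drop=True)
            order = order.sort_values(
                by="distance_ratio", kind="stable"
            )
            ratios = order["distance_ratio"].to_numpy(dtype=float)
            csum = np.cumsum(ratios)
            n = len(ratios)
            keep_n = n
            while keep_n > 1 and csum[keep_n - 1] / keep_n >= ref_mean:
                keep_n -= 1
            if csum[keep_n - 1] / keep_n >= ref_mean:
                unmatchable.append(str(pid))
            kept = order.iloc[:keep_n]
            n_disc = n - keep_n
            if n_disc:
                # reverse the sorted tail so rows appear in removal order
                # (most distant first, later-indexed first among ties)
                discarded_parts.append(order.iloc[keep_n:][::-1])
        kept_parts.append(kept)
        summary.append({
            "patient_id": pid,
            "n_kept": len(kept),
            "n_discarded": n_disc,
            "mean_ratio": float(kept["distance_ratio"].mean()),
        })

    kept_df = pd.concat(kept_parts, ignore_index=True)
    discarded_df = (
        pd.concat(discarded_parts, ignore_index=True)
        if discarded_parts else table.iloc[0:0].copy()
    )
    return MatchResult(
        kept=kept_df, discarded=discarded_df,
        reference_id=reference_id, reference_mean=ref_mean,
        unmatchable=unmatchable,
        per_patient=pd.DataFrame(summary),
    )


def build_patient_profiles(match: MatchResult | pd.DataFrame) -> pd.DataFrame:
    """Per-patient means of d0 and theta2 (arterioles and venules pooled).

    Returns one row per patient with ``mean_parent_diameter``,
    ``mean_smaller_child_deflection``, ``mean_distance_ratio``, ``n_kept``
    and ``n_discarded``.
    """
    if isinstance(match, MatchResult):
        kept = match.kept
        n_disc = dict(zip(match.per_patient["patient_id"],
                          match.per_patient["n_discarded"]))
    else:
        kept = match
        n_disc = {}
    g = kept.groupby("patient_id", observed=True)
    out = pd.DataFrame({
        "mean_parent_diameter": g["d0"].mean(),
        "mean_smaller_child_deflection": g["theta2"].mean(),
        "mean_distance_ratio": g["distance_ratio"].mean(),
        "n_kept": g.size(),
    }).reset_index()
    out["patient_id"] = out["patient_id"].astype(str)
    out["n_discarded"] = out["patient_id"].map(n_disc).fillna(0).astype(int)
    return out.sort_values("patient_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# leave-one-out classification
# ---------------------------------------------------------------------------

def model_labels(patients: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """Binary labels for a model: positive = retinopathy present (model one)
    or PDR (model two, retinopathy cases only)."""
    p = patients.copy()
    if model_id == "one":
        p["label"] = (p["grade"] != "NoDR").astype(int)
    elif model_id == "two":
        p = p[p["grade"] != "NoDR"].copy()
        p["label"] = (p["grade"] == "PDR").astype(int)
    else:
        raise ValueError(f"model_id must be 'one' or 'two', got {model_id!r}")
    return p[["patient_id", "label"]]


def loo_classify(
    profiles: pd.DataFrame,
    labels: pd.DataFrame,
    predictors: list[str] | None = None,
    model_id: str = "one",
    threshold: float = 0.5,
    extra_negatives: pd.DataFrame | None = None,
) -> ClassificationReport:
    """Leave-one-out logistic classification of patient profiles.

    For each patient a logistic model is fitted on all other patients and the
    held-out patient's probability of the positive class computed; the class
    is decided at *threshold*.  Sensitivity/specificity are percentages over
    true positives/negatives.  A fold whose training data lacks one class is
    excluded with a warning.  With *extra_negatives* (model two: held-out
    no-retinopathy profiles) a final model fitted on all labelled patients
    scores them as additional negatives for ``overall_specificity``.
    """
    if predictors is None:
        predictors = MODEL_PREDICTORS[model_id]
    df = profiles.merge(labels, on="patient_id", how="inner")
    df = df.sort_values("patient_id").reset_index(drop=True)
    if df["label"].nunique() < 2:
        raise ValueError("need both classes present")
    for cls in (0, 1):
        if (df["label"] == cls).sum() < 2:
            raise ValueError(f"need >= 2 patients in class {cls}")

    X = df[predictors].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int)
    n = len(df)
    Xc = np.column_stack([np.ones(n), X])

    preds: list[LooPrediction] = []
    fold_coefs: dict[str, list[float]] = {}
    warns: list[str] = []
    n_excluded = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warns.append(f"fold {df['patient_id'][i]}: single-class training set")
            n_excluded += 1
            continue
        fit = fit_logistic(Xc[mask], y[mask].astype(float))
        prob = float(predict_proba(fit, Xc[i:i + 1])[0])
        preds.append(LooPrediction(
            patient_id=str(df["patient_id"][i]),
            true_class=int(y[i]),
            predicted_class=int(prob > threshold),
            predicted_probability=prob,
        ))
        fold_coefs[str(df["patient_id"][i])] = [float(b) for b in fit.beta]

    pos = [p for p in preds if p.true_class == 1]
    neg = [p for p in preds if p.true_class == 0]
    sens = 100.0 * sum(p.predicted_class == 1 for p in pos) / len(pos) if pos else np.nan
    spec = 100.0 * sum(p.predicted_class == 0 for p in neg) / len(neg) if neg else np.nan

    overall_spec = None
    if extra_negatives is not None and len(extra_negatives):
        final = fit_logistic(Xc, y.astype(float))
        Xe = np.column_stack([
            np.ones(len(extra_negatives)),
            extra_negatives[predictors].to_numpy(dtype=float),
        ])
        probs = predict_proba(final, Xe)
        extra_correct = int(np.sum(probs <= threshold))
        total_neg = len(neg) + len(extra_negatives)
        overall_spec = 100.0 * (
            sum(p.predicted_class == 0 for p in neg) + extra_correct
        ) / total_neg

    if warns:
        for w in warns:
            warnings.warn(w, stacklevel=2)
    return ClassificationReport(
        model_id=model_id, sensitivity=float(sens), specificity=float(spec),
        predictions=preds, fold_coefficients=fold_coefs,
        predictors=list(predictors), threshold=threshold,
        warnings=warns, overall_specificity=overall_spec,
        n_excluded_folds=n_excluded,
    )
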