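"""Cohort-level statistics: group summaries, one-way ANOVA with Fisher-protected
LSD post-hoc comparisons, nested risk-factor regressions, progression logistic
odds ratios and repeatability coefficients of variation.

The unit of analysis is the individual bifurcation, pooled within patients
(patient-level clustering is deliberately not modelled; see the warning
attached to every regression result).  All p-values are two-sided and the
default significance level is alpha = 0.05.  Categorical covariates are coded
0/1 with female = 1, type-2 diabetes = 1, condition present = 1; the coding
string travels with every regression result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .types import ANGLE_FEATURES, GEOMETRY_FEATURES, GRADES, WIDTH_FEATURES

COVARIATE_CODING = (
    "sex: female=1, male=0; diabetes_type: type2=1, type1=0; "
    "hypertension/high_cholesterol: present=1, absent=0"
)

CLUSTERING_WARNING = (
    "unit of analysis is the bifurcation pooled within patients; "
    "patient-level clustering is not modelled, so standard errors may be "
    "anti-conservative"
)

#: Nested covariate sets for the three risk-factor models.
MODEL_COVARIATES: dict[int, list[str]] = {
    1: ["age", "sex_female"],
    2: ["age", "sex_female", "diabetes_type2", "hypertension"],
    3: ["age", "sex_female", "diabetes_type2", "hypertension",
        "duration", "high_cholesterol"],
}


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    ms_within: float
    grand_mean: float


@dataclass
class PosthocResult:
    pairwise_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    letters: dict[str, str]
    protected: bool  # True when the omnibus ANOVA gated the pairwise tests


@dataclass
class RegressionResult:
    model_id: int
    feature: str
    coefficients: pd.DataFrame  # index covariate; columns coef, se, t, p
    n: int
    r_squared: float
    coding: str = COVARIATE_CODING
    warning: str = CLUSTERING_WARNING


@dataclass
class LogisticFit:
    feature: str
    coefficient: float
    se: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p: float
    n: int
    penalized: bool = False
    stratum: str = "all"


@dataclass
class RepeatabilityResult:
    per_feature_cov: dict[str, float]  # percent
    family_cov: dict[str, float]       # percent, averaged within feature family
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# summaries and ANOVA
# ---------------------------------------------------------------------------

def _apply_stratum(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return table
    if stratum not in ("arteriole", "venule"):
        raise ValueError(f"stratum must be all|arteriole|venule, got {stratum!r}")
    return table[table["vessel_type"] == stratum]


def summarize_groups(
    table: pd.DataFrame,
    patients: pd.DataFrame,
    features: Sequence[str] = tuple(GEOMETRY_FEATURES),
    grouping: str = "grade",
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-group mean, SD and n for each feature, bifurcation-level.

    Missing values (e.g. junction exponents with no finite root) are excluded
    from the mean/SD with the exclusion count reported in ``n_missing``.
    Groups with no rows are reported absent (omitted), never as zero.
    """
    merged = _apply_stratum(table, stratum).merge(
        patients[["patient_id", grouping]], on="patient_id", how="left"
    )
    rows = []
    for level, sub in merged.groupby(grouping, observed=True, sort=False):
        for feat in features:
            vals = sub[feat]
            rows.append({
                grouping: level,
                "feature": feat,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.notna().sum() > 1 else 0.0,
                "n": int(vals.notna().sum()),
                "n_missing": int(vals.isna().sum()),
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        order = {g: i for i, g in enumerate(GRADES)}
        out = out.sort_values(
            by=[grouping, "feature"],
            key=lambda s: s.map(order) if s.name == grouping else s,
            kind="stable",
        ).reset_index(drop=True)
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from explicit sums of squares."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = [a.size for a in arrays]
    if any(n < 1 for n in ns):
        empty = [g for g, n in zip(names, ns) if n < 1]
        raise ValueError(f"ANOVA groups with no observations: {empty}")
    n_total = sum(ns)
    k = len(arrays)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValueError("ANOVA needs at least 1 within-group df")

    grand = sum(float(a.sum()) for a in arrays) / n_total
    ss_between = sum(n * (float(a.mean()) - grand) ** 2 for a, n in zip(arrays, ns))
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        F = 0.0 if ms_between == 0.0 else np.inf
    else:
        F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), df_between=df_between, df_within=df_within, p=p,
        group_means={g: float(a.mean()) for g, a in zip(names, arrays)},
        group_sds={g: float(a.std(ddof=1)) if a.size > 1 else 0.0
                   for g, a in zip(names, arrays)},
        group_ns=dict(zip(names, ns)),
        ms_within=float(ms_within), grand_mean=float(grand),
    )


def _subset_letters(
    names: list[str],
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Homogeneous-subset letters: groups sorted by mean; every maximal run of
    mutually non-different groups shares one letter."""
    order = sorted(names, key=lambda g: means[g])

    def differ(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    intervals: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not any(
            differ(order[a], order[b])
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        intervals.append((i, j))
    # keep only maximal intervals
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    maximal = sorted(set(maximal))
    letters: dict[str, list[str]] = {g: [] for g in names}
    for idx, (i, j) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for g in order[i:j + 1]:
            letters[g].append(letter)
    return {g: "".join(v) for g, v in letters.items()}


def flsd_posthoc(
    groups: Mapping[str, Sequence[float]],
    anova: AnovaResult,
    alpha: float = 0.05,
) -> PosthocResult:
    """Fisher-protected least-significant-difference pairwise comparisons.

    Pairwise two-sided t-tests use the pooled within-group mean square and its
    df from the omnibus ANOVA, and are honoured only when the omnibus p is at
    most *alpha* — otherwise every pair is reported non-significant (the
    "protection").  Homogeneous-subset letters summarise the pairwise matrix.
    """
    names = list(groups)
    if set(names) != set(anova.group_ns):
        raise ValueError("groups do not match the supplied ANOVA result")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    arrays = {g: a[np.isfinite(a)] for g, a in arrays.items()}
    for g, a in arrays.items():
        if a.size != anova.group_ns[g]:
            raise ValueError(f"group {g!r} size differs from the ANOVA result")

    protected = anova.p <= alpha
    pairwise_p: dict[tuple[str, str], float] = {}
    significant: dict[tuple[str, str], bool] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = anova.group_ns[a], anova.group_ns[b]
            se = np.sqrt(anova.ms_within * (1.0 / na + 1.0 / nb))
            if se == 0.0:
                p = 1.0 if anova.group_means[a] == anova.group_means[b] else 0.0
            else:
                t = (anova.group_means[a] - anova.group_means[b]) / se
                p = 2.0 * float(sps.t.sf(abs(t), anova.df_within))
            pairwise_p[(a, b)] = p
            significant[(a, b)] = bool(protected and p <= alpha)
    letters = _subset_letters(names, anova.group_means, significant)
    return PosthocResult(pairwise_p, significant, letters, protected)


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

def _design_frame(table: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    pat = patients.copy()
    pat["sex_female"] = (pat["sex"] == "female").astype(float)
    pat["diabetes_type2"] = (pat["diabetes_type"].astype(int) == 2).astype(float)
    pat["hypertension"] = pat["hypertension"].astype(float)
    pat["high_cholesterol"] = pat["high_cholesterol"].astype(float)
    cols = ["patient_id", "age", "sex_female", "diabetes_type2",
            "hypertension", "duration", "high_cholesterol"]
    return table.merge(pat[cols], on="patient_id", how="left")


def fit_risk_factor_models(
    table: pd.DataFrame,
    patients: pd.DataFrame,
    feature: str,
    model_id: int,
    stratum: str = "all",
    unit: str = "bifurcation",
) -> RegressionResult:
    """OLS of a geometry feature on the nested demographic/clinical models.

    Model 1: age + sex; model 2 adds diabetes type + hypertension history;
    model 3 adds diabetes duration + hypercholesterolemia history.  ``unit``
    switches between bifurcation-level rows (default) and per-image feature
    means.
    """
    if model_id not in MODEL_COVARIATES:
        raise ValueError(f"model_id must be 1|2|3, got {model_id}")
    covs = MODEL_COVARIATES[model_id]
    df = _design_frame(_apply_stratum(table, stratum), patients)
    if unit == "image":
        grouped = df.groupby("image_id", observed=True)
        df = grouped[[feature] + covs].mean().reset_index()
    elif unit != "bifurcation":
        raise ValueError(f"unit must be bifurcation|image, got {unit!r}")
    df = df.dropna(subset=[feature] + covs)

    X = df[covs].to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(df)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        collinear = [c for i, c in enumerate(covs)
                     if np.linalg.matrix_rank(np.delete(Xc, i + 1, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    res = sm.OLS(df[feature].to_numpy(dtype=float),
                 sm.add_constant(df[covs], has_constant="add")).fit()
    coef = pd.DataFrame({
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    return RegressionResult(
        model_id=model_id, feature=feature, coefficients=coef,
        n=int(res.nobs), r_squared=float(res.rsquared),
    )


def fit_progression_logistic(
    table: pd.DataFrame,
    patients: pd.DataFrame,
    feature: str,
    stratum: str = "all",
) -> LogisticFit:
    """Binary logistic odds ratio for progression from one baseline feature.

    Fits progression status (patient-level flag, repeated over that patient's
    baseline bifurcations) on the bifurcation-level feature; the odds ratio is
    per unit of the feature with a Wald 95% CI.  Complete separation is
    retried with a small ridge penalty (1e-6) and flagged ``penalized``.
    """
    df = _apply_stratum(table, stratum)
    if "visit" in df.columns:
        df = df[df["visit"] == "baseline"]
    df = df.merge(patients[["patient_id", "progressor"]], on="patient_id")
    df = df.dropna(subset=[feature, "progressor"])
    y = df["progressor"].astype(float).to_numpy()
    x = df[feature].to_numpy(dtype=float)
    X = sm.add_constant(x)

    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged or not np.all(np.isfinite(res.bse)) \
                or np.max(np.abs(res.params)) > 30:
            raise RuntimeError("divergent fit")
        coef, se = float(res.params[1]), float(res.bse[1])
        p = float(res.pvalues[1])
    except Exception:
        from .logistic import fit_logistic
        fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y)
        penalized = True
        coef = float(fit.beta[1])
        se = float(np.sqrt(fit.cov[1, 1])) if fit.cov is not None else np.nan
        p = 2.0 * float(sps.norm.sf(abs(coef / se))) if np.isfinite(se) else np.nan

    z = float(sps.norm.ppf(0.975))
    return LogisticFit(
        feature=feature, coefficient=coef, se=se,
        odds_ratio=float(np.exp(coef)),
        ci95_low=float(np.exp(coef - z * se)),
        ci95_high=float(np.exp(coef + z * se)),
        p=p, n=len(df), penalized=penalized, stratum=stratum,
    )


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

FEATURE_FAMILIES = {"widths": WIDTH_FEATURES, "angles": ANGLE_FEATURES}


def repeatability_cov(
    sessions: pd.DataFrame,
    features: Sequence[str] | None = None,
    families: Mapping[str, Sequence[str]] = FEATURE_FAMILIES,
) -> RepeatabilityResult:
    """Intra-observer coefficient of variation from repeated markings.

    *sessions* is long-format with a ``bifurcation_id`` column, a ``session``
    column and one column per feature.  For each feature the within-bifurcation
    SD is the square root of the one-way-ANOVA within-group mean square
    (bifurcations as groups, sessions as replicates); CoV is that SD over the
    grand mean, in percent, then averaged within each feature family (widths;
    angles).  Bifurcations with a single session are excluded with a warning.
    """
    if features is None:
        features = sorted({f for fam in families.values() for f in fam
                           if f in sessions.columns})
    counts = sessions.groupby("bifurcation_id", observed=True).size()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(
            f"excluding {len(singletons)} bifurcation(s) with a single session",
            stacklevel=2,
        )
    df = sessions[~sessions["bifurcation_id"].isin(singletons)]
    if df.empty:
        raise ValueError("no bifurcation has >= 2 sessions")

    per_feature: dict[str, float] = {}
    for feat in features:
        ss_within = 0.0
        df_within = 0
        total = 0.0
        n_total = 0
        for _, sub in df.groupby("bifurcation_id", observed=True):
            vals = sub[feat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                continue
            ss_within += float(((vals - vals.mean()) ** 2).sum())
            df_within += vals.size - 1
            total += float(vals.sum())
            n_total += vals.size
        grand_mean = total / n_total
        within_sd = np.sqrt(ss_within / df_within)
        per_feature[feat] = 100.0 * within_sd / abs(grand_mean)

    family_cov = {
        fam: float(np.mean([per_feature[f] for f in feats if f in per_feature]))
        for fam, feats in families.items()
        if any(f in per_feature for f in feats)
    }
    return RepeatabilityResult(per_feature, family_cov, n_excluded=len(singletons))
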