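"""Composite digital measure construction and its evaluation battery.

The composite is a gaussian GEE (exchangeable working correlation) of the
clinical anchor on the merged, standardized feature set plus covariates;
its linear predictor is the composite digital score.  Evaluation covers
progression (the screening LMM refit with the composite as response,
Cohen's d effect sizes on subject-level slopes, between/within-subject
coefficients of variation from a one-way variance decomposition) and
classification of de novo PD vs healthy controls (Mann-Whitney AUC and a
Youden-optimal threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats

from .gee import fit_gee
from .lmm import LMMFit, fit_progression_lmm
from .selection import subject_folds

__all__ = [
    "CompositeModel",
    "EvaluationReport",
    "fit_composite",
    "score",
    "crossvalidated_scores",
    "evaluate_progression",
    "effect_size_slope",
    "coefficient_of_variation",
    "classify",
    "roc_points",
    "evaluate_composite",
]


@dataclass
class CompositeModel:
    features: list
    covariates: list
    coef: dict                 # name -> coefficient (standardized feature scale)
    center: dict               # feature -> training mean
    scale: dict                # feature -> training SD
    family: str = "gaussian"
    include_covariates_in_score: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "CompositeModel":
        return cls(**json.loads(s))


@dataclass
class EvaluationReport:
    p_group_by_visit: float = np.nan
    p_hc_slope: float = np.nan
    p_diff_slopes: dict = field(default_factory=dict)
    effect_sizes: dict = field(default_factory=dict)   # group -> (d, lo, hi)
    between_cov: float = np.nan
    within_cov: float = np.nan
    rmse_by_group: dict = field(default_factory=dict)
    auc: float = np.nan
    threshold: float = np.nan
    confusion: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=float)


def fit_composite(data: pd.DataFrame, final_features, covariates=("age",)
                  ) -> CompositeModel:
    """GEE of the clinical score on standardized features + covariates."""
    final_features = list(final_features)
    covariates = list(covariates)
    missing = [f for f in final_features if f not in data.columns]
    if missing:
        raise ValueError(f"features not in data: {missing}")
    center = {f: float(data[f].mean()) for f in final_features}
    scale = {f: float(data[f].std(ddof=0)) for f in final_features}
    zero = [f for f in final_features if scale[f] == 0]
    if zero:
        raise ValueError(f"constant features cannot be standardized: {zero}")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for c in covariates:
        cols.append(data[c].to_numpy(float))
        names.append(c)
    for f in final_features:
        cols.append((data[f].to_numpy(float) - center[f]) / scale[f])
        names.append(f)
    X = np.column_stack(cols)
    fit = fit_gee(X, data["clinical_score"].to_numpy(float),
                  data["subject_id"].to_numpy(), family="gaussian",
                  corstr="exchangeable", column_names=names)
    return CompositeModel(final_features, covariates,
                          dict(zip(names, map(float, fit.params))),
                          center, scale)


def score(model: CompositeModel, rows: pd.DataFrame) -> np.ndarray:
    """Composite digital score (linear predictor) for subject-visit rows."""
    out = np.full(len(rows), model.coef["intercept"], dtype=float)
    if model.include_covariates_in_score:
        for c in model.covariates:
            out += model.coef[c] * rows[c].to_numpy(float)
    for f in model.features:
        if f not in rows.columns:
            raise ValueError(f"missing feature column {f!r}")
        sd = model.scale[f]
        if sd == 0:
            raise ValueError(f"stored SD is zero for feature {f!r}")
        out += model.coef[f] * (rows[f].to_numpy(float) - model.center[f]) / sd
    return out


def crossvalidated_scores(
    data: pd.DataFrame,
    final_features,
    covariates=("age",),
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every subject with the model trained without that subject.

    Returns the dataset with a ``composite_score`` column; per-group RMSE
    versus the clinical anchor is attached as ``.attrs['rmse_by_group']``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    out = data.copy()
    out["composite_score"] = np.nan
    for held in subject_folds(data, n_folds, seed):
        test = data["subject_id"].isin(held).to_numpy()
        model = fit_composite(data.loc[~test], final_features, covariates)
        out.loc[test, "composite_score"] = score(model, data.loc[test])
    rmse = {}
    for g, block in out.groupby("group", sort=True):
        err = block["composite_score"] - block["clinical_score"]
        rmse[g] = float(np.sqrt(np.mean(err**2)))
    pd_mask = out["group"] != "hc"
    err = out.loc[pd_mask, "composite_score"] - out.loc[pd_mask, "clinical_score"]
    rmse["pd_combined"] = float(np.sqrt(np.mean(err**2)))
    out.attrs["rmse_by_group"] = rmse
    return out


def evaluate_progression(scored: pd.DataFrame, covariates=("age",)) -> LMMFit:
    """Refit the screening LMM with the composite score as response."""
    return fit_progression_lmm(scored, "composite_score", covariates)


def effect_size_slope(scored: pd.DataFrame, pd_group: str,
                      value: str = "composite_score",
                      reference: str = "hc"):
    """Cohen's d between per-subject OLS slopes of two groups.

    Returns ``(d, ci_low, ci_high)``; the 95% CI uses the standard
    large-sample SE of d.  Subjects with < 2 visits are excluded.
    """
    slopes = {g: [] for g in (pd_group, reference)}
    sub = scored[scored["group"].isin(slopes)]
    for (sid, g), block in sub.groupby(["subject_id", "group"], observed=True):
        t = block["visit_time"].to_numpy(float)
        y = block[value].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.sum() < 2 or len(np.unique(t[ok])) < 2:
            continue
        slopes[g].append(float(np.polyfit(t[ok], y[ok], 1)[0]))
    s1, s0 = np.asarray(slopes[pd_group]), np.asarray(slopes[reference])
    n1, n0 = len(s1), len(s0)
    if min(n1, n0) < 2:
        raise ValueError("need >= 2 subjects with slopes in each group")
    sp = np.sqrt(((n1 - 1) * s1.var(ddof=1) + (n0 - 1) * s0.var(ddof=1))
                 / (n1 + n0 - 2))
    d = float((s1.mean() - s0.mean()) / sp)
    se = np.sqrt((n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0 - 2)))
    return d, d - 1.96 * se, d + 1.96 * se


def coefficient_of_variation(scored: pd.DataFrame,
                             value: str = "composite_score"):
    """Between- and within-subject CoV from a one-way variance
    decomposition of the score by subject (method-of-moments ANOVA).

    Unbalanced designs use the standard n0 = (N - sum n_i^2 / N)/(k - 1)
    coefficient; a negative between-subject component is clipped at 0.
    """
    y = scored[value].to_numpy(float)
    grand = float(np.nanmean(y))
    if grand <= 0:
        raise ValueError(
            "grand mean of the score is not positive; CoV undefined — shift "
            "the score explicitly before computing CoV")
    groups = [b[value].dropna().to_numpy(float)
              for _, b in scored.groupby("subject_id")]
    groups = [g for g in groups if g.size > 0]
    k = len(groups)
    N = sum(g.size for g in groups)
    if k < 2 or N <= k:
        raise ValueError("need >= 2 subjects and replicate visits")
    means = np.array([g.mean() for g in groups])
    sizes = np.array([g.size for g in groups])
    ssb = float(np.sum(sizes * (means - np.sum(sizes * means) / N) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    sigma2_b = max((msb - msw) / n0, 0.0)
    return float(np.sqrt(sigma2_b) / grand), float(np.sqrt(msw) / grand)


def roc_points(scored: pd.DataFrame, positive_group: str = "de_novo_pd",
               negative_group: str = "hc",
               value: str = "composite_score") -> pd.DataFrame:
    """ROC curve over pooled subject-visit scores: one row per candidate
    threshold with its TPR and FPR (positive called at score >= threshold)."""
    sub = scored[scored["group"].isin([positive_group, negative_group])]
    y = (sub["group"] == positive_group).to_numpy()
    s = sub[value].to_numpy(float)
    ok = ~np.isnan(s)
    y, s = y[ok], s[ok]
    pos, neg = s[y], s[~y]
    rows = [{"threshold": -np.inf, "tpr": 1.0, "fpr": 1.0}]
    for t in np.sort(np.unique(s)):
        rows.append({"threshold": float(t),
                     "tpr": float(np.mean(pos >= t)),
                     "fpr": float(np.mean(neg >= t))})
    return pd.DataFrame(rows)


def classify(scored: pd.DataFrame, positive_group: str = "de_novo_pd",
             negative_group: str = "hc", value: str = "composite_score"):
    """AUC (Mann-Whitney), Youden-optimal threshold, confusion counts.

    Pooled subject-visit scores; the threshold maximizing J = TPR - FPR,
    ties resolved toward the lower threshold; rows with score >= threshold
    are called positive.
    """
    sub = scored[scored["group"].isin([positive_group, negative_group])]
    y = (sub["group"] == positive_group).to_numpy()
    s = sub[value].to_numpy(float)
    ok = ~np.isnan(s)
    y, s = y[ok], s[ok]
    if y.all() or not y.any():
        raise ValueError("both groups must be present")
    pos, neg = s[y], s[~y]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u / (len(pos) * len(neg)))
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(s)):
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    pred = s >= best_t
    confusion = {
        "tp": int(np.sum(pred & y)), "fp": int(np.sum(pred & ~y)),
        "fn": int(np.sum(~pred & y)), "tn": int(np.sum(~pred & ~y)),
    }
    return auc, best_t, confusion


def evaluate_composite(scored: pd.DataFrame, covariates=("age",),
             positive_group: str = "de_novo_pd") -> EvaluationReport:
    """Full evaluation battery on a cross-validated scored dataset."""
    report = EvaluationReport()
    fit = evaluate_progression(scored, covariates)
    report.p_group_by_visit = fit.p_interaction
    report.p_hc_slope = fit.p_hc_slope
    report.p_diff_slopes = {g: v[2] for g, v in fit.diff_slopes.items()}
    for g in fit.diff_slopes:
        try:
            report.effect_sizes[g] = effect_size_slope(scored, g)
        except ValueError:
            pass
    try:
        report.between_cov, report.within_cov = coefficient_of_variation(scored)
    except ValueError:
        pass
    report.rmse_by_group = dict(scored.attrs.get("rmse_by_group", {}))
    try:
        report.auc, report.threshold, report.confusion = classify(
            scored, positive_group=positive_group)
    except ValueError:
        pass
    return report
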