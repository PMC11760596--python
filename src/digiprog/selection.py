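"""Feature ranking, cross-validated feature-count selection, and merging.

Candidate features that survive univariate screening are ranked by the
magnitude of their (standardized-scale) penalized-GEE estimates.  The
number of top features P to carry into the composite is chosen by
subject-level, group-stratified cross-validation: within each fold a
PGEE is fit on the training subjects, features are re-ranked, and for
each candidate k an unpenalized GEE on the top-k features is scored on
the held-out subjects (RMSE for the continuous endpoint, AUC for the
binary de-novo-vs-HC endpoint).  Progression- and classification-derived
feature sets are merged by order-preserving union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .gee import PGEEFit, fit_gee, fit_pgee, tune_lambda

__all__ = [
    "FeatureRanking",
    "CVCurve",
    "rank_features",
    "choose_feature_count",
    "choose_from_curve",
    "final_ranking",
    "select_final_features",
    "merge_feature_sets",
    "subject_folds",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.7, 1.0)


@dataclass
class FeatureRanking:
    features: list          # descending |estimate|, ties by name ascending
    estimates: list
    endpoint: str = "progression"


@dataclass
class CVCurve:
    counts: np.ndarray
    fold_scores: np.ndarray   # (n_folds, len(counts))
    mean_scores: np.ndarray
    chosen: int
    metric: str               # "rmse" or "auc"


def rank_features(fit: PGEEFit, feature_names=None, endpoint="progression"
                  ) -> FeatureRanking:
    """Order penalized features by descending |estimate|; drop zeros.

    Estimates are on the standardized scale when the fit standardized its
    columns.  Ties break by feature name ascending.
    """
    pen = np.asarray(fit.penalized_index, int)
    names = feature_names or [
        fit.column_names[j] if fit.column_names else f"x{j}" for j in pen
    ]
    est = fit.params[pen]
    keep = np.abs(est) > fit.zero_cutoff
    pairs = sorted(
        ((float(e), str(n)) for e, n in zip(est[keep], np.asarray(names)[keep])),
        key=lambda t: (-abs(t[0]), t[1]),
    )
    return FeatureRanking([n for _, n in pairs], [e for e, _ in pairs], endpoint)


def subject_folds(data: pd.DataFrame, n_folds: int, seed: int) -> list[np.ndarray]:
    """Group-stratified subject-level folds (arrays of subject ids)."""
    rng = np.random.default_rng(seed)
    subj = data[["subject_id", "group"]].drop_duplicates()
    folds: list[list] = [[] for _ in range(n_folds)]
    offset = 0
    for _, block in subj.groupby("group", sort=True):
        ids = block["subject_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        for i, s in enumerate(ids):
            folds[(i + offset) % n_folds].append(s)
        offset += len(ids)
    return [np.asarray(f) for f in folds]


def _design(data, features, covariates):
    cols = list(covariates) + list(features)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float)
                                                for c in cols])
    return X, ["intercept"] + cols


def choose_feature_count(
    data: pd.DataFrame,
    candidate_features,
    endpoint: str = "progression",
    response: str = "clinical_score",
    covariates=("age",),
    k_max: int = 20,
    n_folds: int = 10,
    seed: int = 0,
    lam_grid=DEFAULT_LAMBDA_GRID,
    positive_group: str = "de_novo_pd",
    negative_group: str = "hc",
    corstr: str | None = None,
) -> CVCurve:
    """Pick the number of top-ranked features by cluster-level CV.

    For the binary endpoint only the positive/negative groups enter, the
    response is group membership, and the metric is AUC (maximized); for
    the continuous endpoint the metric is RMSE (minimized).  Ties go to
    the smaller k.  The penalty level is tuned once on the full data
    (shared lambda grid; no nested tuning).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    candidate_features = list(candidate_features)
    if endpoint == "classification":
        data = data[data["group"].isin([positive_group, negative_group])]
        y_all = (data["group"] == positive_group).to_numpy(float)
        family = "binomial"
        corstr = corstr or "independence"
        metric = "auc"
    else:
        y_all = data[response].to_numpy(float)
        family = "gaussian"
        corstr = corstr or "exchangeable"
        metric = "rmse"
    k_max = min(k_max, len(candidate_features))
    counts = np.arange(1, k_max + 1)
    X_all, names = _design(data, candidate_features, covariates)
    clusters_all = data["subject_id"].to_numpy()
    pen_idx = np.arange(1 + len(covariates), X_all.shape[1])

    lam_star, _ = tune_lambda(
        X_all, y_all, clusters_all, family=family, corstr=corstr,
        lam_grid=lam_grid, penalized_index=pen_idx, seed=seed,
    )

    folds = subject_folds(data, n_folds, seed)
    scores = np.full((len(folds), k_max), np.nan)
    for f, held in enumerate(folds):
        test = data["subject_id"].isin(held).to_numpy()
        train = ~test
        assert not np.intersect1d(clusters_all[train], clusters_all[test]).size
        pfit = fit_pgee(
            X_all[train], y_all[train], clusters_all[train], family=family,
            corstr=corstr, lam=lam_star, penalized_index=pen_idx,
        )
        ranking = rank_features(pfit, feature_names=candidate_features)
        order = ranking.features or sorted(candidate_features)
        for k in counts:
            top = list(order[:k])
            if len(top) < k:  # fewer nonzero estimates than k: pad by name order
                rest = [c for c in sorted(candidate_features) if c not in top]
                top += rest[: k - len(top)]
            Xk, _ = _design(data, top, covariates)
            gfit = fit_gee(Xk[train], y_all[train], clusters_all[train],
                           family=family, corstr=corstr)
            pred = Xk[test] @ gfit.params
            if metric == "rmse":
                scores[f, k - 1] = float(np.sqrt(np.mean((y_all[test] - pred) ** 2)))
            else:
                if len(np.unique(y_all[test])) < 2:
                    continue  # degenerate fold: leave as NaN
                scores[f, k - 1] = float(roc_auc_score(y_all[test], expit(pred)))
    mean_scores = np.nanmean(scores, axis=0)
    chosen = choose_from_curve(counts, mean_scores, metric)
    return CVCurve(counts, scores, mean_scores, chosen, metric)


def choose_from_curve(counts, mean_scores, metric: str) -> int:
    """Optimum of a mean CV curve: argmin for rmse, argmax for auc;
    ties resolved toward the smaller feature count."""
    counts = np.asarray(counts)
    mean_scores = np.asarray(mean_scores, float)
    if metric == "rmse":
        hits = mean_scores <= np.nanmin(mean_scores) + 1e-12
    else:
        hits = mean_scores >= np.nanmax(mean_scores) - 1e-12
    return int(counts[np.flatnonzero(hits).min()])


def final_ranking(
    data: pd.DataFrame,
    candidate_features,
    endpoint: str = "progression",
    response: str = "clinical_score",
    covariates=("age",),
    lam_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    positive_group: str = "de_novo_pd",
    negative_group: str = "hc",
) -> FeatureRanking:
    """Whole-dataset PGEE ranking at the CV-tuned penalty level."""
    candidate_features = list(candidate_features)
    if endpoint == "classification":
        sub = data[data["group"].isin([positive_group, negative_group])]
        y = (sub["group"] == positive_group).to_numpy(float)
        family, corstr = "binomial", "independence"
    else:
        sub = data
        y = sub[response].to_numpy(float)
        family, corstr = "gaussian", "exchangeable"
    X, _ = _design(sub, candidate_features, covariates)
    clusters = sub["subject_id"].to_numpy()
    pen = np.arange(1 + len(covariates), X.shape[1])
    lam, _ = tune_lambda(X, y, clusters, family=family, corstr=corstr,
                         lam_grid=tuple(lam_grid), penalized_index=pen,
                         seed=seed)
    fit = fit_pgee(X, y, clusters, family=family, corstr=corstr, lam=lam,
                   penalized_index=pen)
    return rank_features(fit, feature_names=candidate_features,
                         endpoint=endpoint)


def select_final_features(
    data: pd.DataFrame,
    candidate_features,
    covariates=("age",),
    k_max: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    lam_grid=DEFAULT_LAMBDA_GRID,
    positive_group: str = "de_novo_pd",
    negative_group: str = "hc",
) -> dict:
    """Both-endpoint feature selection: CV-chosen counts, whole-data
    rankings, and the merged final feature set."""
    out: dict = {}
    for endpoint in ("progression", "classification"):
        curve = choose_feature_count(
            data, candidate_features, endpoint=endpoint,
            covariates=covariates, k_max=k_max, n_folds=n_folds, seed=seed,
            lam_grid=lam_grid, positive_group=positive_group,
            negative_group=negative_group)
        ranking = final_ranking(
            data, candidate_features, endpoint=endpoint,
            covariates=covariates, lam_grid=lam_grid, seed=seed,
            positive_group=positive_group, negative_group=negative_group)
        out[endpoint] = {"curve": curve, "chosen_p": curve.chosen,
                         "features": ranking.features[: curve.chosen]}
    out["final_features"] = merge_feature_sets(
        out["progression"]["features"], out["classification"]["features"])
    return out


def merge_feature_sets(progression_set, classification_set) -> list[str]:
    """Order-preserving union (progression first); duplicates once."""
    seen, merged = set(), []
    for f in list(progression_set) + list(classification_set):
        if f not in seen:
            seen.add(f)
            merged.append(f)
    if not merged:
        raise ValueError("merged feature set is empty; no composite possible")
    return merged
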