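"""Epoch aggregation and the feature quality-control pipeline.

Epoch-level task data (one row per step / turn / sway epoch) are reduced
to subject-visit summary statistics (mean, median, SD, mean absolute
deviation about the mean).  The QC pipeline then runs, in fixed order:

    filter non-informative -> mean-impute -> prune correlated
    -> log-transform skewed -> remove per-value outliers -> re-impute

Non-informative features have too few distinct values, too much
missingness, or extreme values under a robust (median/MAD) z-score.
Correlation pruning is greedy in descending-variance order; skewed
features (adjusted Fisher-Pearson sample skewness beyond a threshold)
are natural-log transformed, shifting first when not strictly positive.
Outlier removal blanks individual values beyond a robust z cutoff and
re-imputes, preserving the longitudinal grid.  No step reorders or drops
subject-visit rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCConfig",
    "QCReport",
    "EmptyPanelError",
    "aggregate_epochs",
    "filter_noninformative",
    "impute_mean",
    "prune_correlated",
    "log_transform_skewed",
    "remove_value_outliers",
    "run_qc_pipeline",
    "feature_columns",
    "ID_COLUMNS",
]

#: columns of a long-format dataset that are not digital features
ID_COLUMNS = ("subject_id", "group", "visit_time", "age", "sex",
              "clinical_score")


class EmptyPanelError(RuntimeError):
    """Raised when QC removes every feature."""


@dataclass
class QCConfig:
    min_distinct_values: int = 5
    max_missing_fraction: float = 0.5
    extreme_value_rule: float = 6.0   # |robust z| flagging a feature
    corr_threshold: float = 0.95
    skew_threshold: float = 2.0
    outlier_winsor_z: float = 4.0     # per-value robust z for removal

    def __post_init__(self):
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in (0, 1)")
        for name in ("min_distinct_values", "extreme_value_rule",
                     "corr_threshold", "skew_threshold", "outlier_winsor_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    disposition: dict = field(default_factory=dict)  # feature -> kept/removed_*
    transform: dict = field(default_factory=dict)    # feature -> none/log/shift_log
    imputed_cells: int = 0
    removed_outlier_values: int = 0

    def kept(self) -> list[str]:
        return [f for f, d in self.disposition.items() if d == "kept"]

    def merge(self, other: "QCReport") -> "QCReport":
        for f, d in other.disposition.items():
            if self.disposition.get(f, "kept") == "kept":
                self.disposition[f] = d
        self.transform.update(other.transform)
        self.imputed_cells += other.imputed_cells
        self.removed_outlier_values += other.removed_outlier_values
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.disposition),
                "disposition": list(self.disposition.values()),
                "transform": [self.transform.get(f, "none")
                              for f in self.disposition],
            }
        )


def feature_columns(data: pd.DataFrame) -> list[str]:
    """Digital-feature columns: everything that is not an identifier,
    covariate, clinical anchor, or clinical subscale column."""
    return [c for c in data.columns
            if c not in ID_COLUMNS and not c.startswith("subscale_")]


def aggregate_epochs(epochs: pd.DataFrame, stats_subset=("mean", "median", "sd", "mad")
                     ) -> pd.DataFrame:
    """Collapse an epoch table to one row per subject-visit.

    Emits one column per (feature, statistic), named
    ``{feature}__{stat}``; ``mad`` is the mean absolute deviation about
    the mean.  A group whose epochs are all missing yields a missing cell.
    """
    allowed = {"mean", "median", "sd", "mad"}
    bad = set(stats_subset) - allowed
    if bad:
        raise ValueError(f"unknown statistics: {sorted(bad)}")

    def _agg(x: pd.Series) -> pd.Series:
        x = x.dropna().to_numpy(float)
        out = {}
        if x.size == 0:
            return pd.Series({s: np.nan for s in stats_subset})
        for s in stats_subset:
            if s == "mean":
                out[s] = x.mean()
            elif s == "median":
                out[s] = float(np.median(x))
            elif s == "sd":
                out[s] = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            elif s == "mad":
                out[s] = float(np.mean(np.abs(x - x.mean())))
        return pd.Series(out)

    g = (epochs.groupby(["subject_id", "visit_time", "feature_name"])["value"]
         .apply(_agg).unstack(level=[-2, -1]))
    g.columns = [f"{feat}__{stat}" for feat, stat in g.columns]
    return g.reset_index()


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def _extreme_scale(obs: np.ndarray, qc: QCConfig) -> np.ndarray:
    """Scale on which extreme values are judged: the log scale for
    strictly positive, heavily skewed features -- those are destined for
    the log-transform step, and a raw-scale robust z would misread the
    long right tail as extreme values."""
    if obs.size and obs.min() > 0 and \
            abs(stats.skew(obs, bias=False)) > qc.skew_threshold:
        return np.log(obs)
    return obs


def filter_noninformative(data: pd.DataFrame, qc: QCConfig | None = None
                          ) -> tuple[pd.DataFrame, QCReport]:
    """Drop features with few distinct values, heavy missingness, or
    extreme values under the robust z rule."""
    qc = qc or QCConfig()
    feats = feature_columns(data)
    if not feats:
        raise EmptyPanelError("dataset has no feature columns")
    report = QCReport()
    drop = []
    for f in feats:
        col = data[f].to_numpy(float)
        obs = col[~np.isnan(col)]
        if len(np.unique(obs)) < qc.min_distinct_values:
            report.disposition[f] = "removed_noninformative"
        elif np.isnan(col).mean() > qc.max_missing_fraction:
            report.disposition[f] = "removed_missing"
        elif np.any(np.abs(_robust_z(_extreme_scale(obs, qc))) >
                    qc.extreme_value_rule):
            report.disposition[f] = "removed_extreme"
        else:
            report.disposition[f] = "kept"
            continue
        drop.append(f)
    out = data.drop(columns=drop)
    if not feature_columns(out):
        raise EmptyPanelError("all features removed by the non-informative filter")
    return out, report


def impute_mean(data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing feature cells with the feature's observed mean."""
    out = data.copy()
    n_imputed = 0
    for f in feature_columns(out):
        col = out[f]
        miss = col.isna()
        if miss.all():
            raise ValueError(f"feature {f!r} has no observed values")
        if miss.any():
            out[f] = col.fillna(col.mean())
            n_imputed += int(miss.sum())
    return out, n_imputed


def prune_correlated(data: pd.DataFrame, corr_threshold: float = 0.95
                     ) -> tuple[pd.DataFrame, QCReport]:
    """Greedy correlation pruning on a complete feature matrix.

    Features are visited in descending variance (ties broken by name);
    a feature correlated beyond the threshold with an already-retained
    feature is dropped, so no retained pair exceeds the threshold.
    """
    feats = feature_columns(data)
    report = QCReport()
    X = data[feats].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("prune_correlated requires a complete (imputed) matrix")
    variances = X.var(axis=0)
    order = sorted(range(len(feats)), key=lambda j: (-variances[j], feats[j]))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    kept: list[int] = []
    for j in order:
        if any(abs(corr[j, k]) > corr_threshold for k in kept):
            report.disposition[feats[j]] = "removed_correlated"
        else:
            kept.append(j)
            report.disposition[feats[j]] = "kept"
    drop = [f for f, d in report.disposition.items() if d != "kept"]
    return data.drop(columns=drop), report


def log_transform_skewed(data: pd.DataFrame, skew_threshold: float = 2.0
                         ) -> tuple[pd.DataFrame, QCReport]:
    """Natural-log transform features with |sample skewness| beyond the
    threshold; non-positive features are shifted by (1 - min) first."""
    out = data.copy()
    report = QCReport()
    for f in feature_columns(out):
        x = out[f].to_numpy(float)
        sk = stats.skew(x[~np.isnan(x)], bias=False)
        if abs(sk) > skew_threshold:
            mn = np.nanmin(x)
            if mn > 0:
                out[f] = np.log(x)
                report.transform[f] = "log"
            else:
                out[f] = np.log(x + (1.0 - mn))
                report.transform[f] = "shift_log"
        else:
            report.transform[f] = "none"
        report.disposition[f] = "kept"
    return out, report


def remove_value_outliers(data: pd.DataFrame, winsor_z: float = 4.0
                          ) -> tuple[pd.DataFrame, int]:
    """Blank individual values with |robust z| beyond the cutoff."""
    out = data.copy()
    n_removed = 0
    for f in feature_columns(out):
        x = out[f].to_numpy(float)
        z = _robust_z(x)
        mask = np.abs(z) > winsor_z
        if mask.any():
            x = x.copy()
            x[mask] = np.nan
            out[f] = x
            n_removed += int(mask.sum())
    return out, n_removed


def run_qc_pipeline(data: pd.DataFrame, qc: QCConfig | None = None
                    ) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline in the fixed order; idempotent on clean data."""
    qc = qc or QCConfig()
    out, report = filter_noninformative(data, qc)
    out, n_imp = impute_mean(out)
    report.imputed_cells += n_imp
    out, r2 = prune_correlated(out, qc.corr_threshold)
    report.merge(r2)
    out, r3 = log_transform_skewed(out, qc.skew_threshold)
    report.merge(r3)
    out, n_out = remove_value_outliers(out, qc.outlier_winsor_z)
    report.removed_outlier_values += n_out
    out, n_imp2 = impute_mean(out)
    report.imputed_cells += n_imp2
    if not feature_columns(out):
        raise EmptyPanelError("no features survived quality control")
    return out, report
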