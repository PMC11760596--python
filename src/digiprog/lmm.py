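"""Linear mixed-effects progression screening and association testing.

Each digital feature is screened with an LMM of the form

    feature ~ covariates + group + time + group:time + covariate:time
              + (1 + time | subject)

fit by REML, with the healthy-control group as the reference level so the
``time`` main effect is the HC slope (covariates are mean-centered first).
A feature passes screening when its HC trajectory is flat (HC slope p >
alpha_hc) and it progresses in the PD groups (omnibus group-by-time Wald
p < alpha_prog, or any PD-vs-HC differential slope p < alpha_prog).

All coefficient p-values are Wald tests on the normal approximation; the
omnibus group-by-time test is a multi-degree-of-freedom Wald chi-square
over the interaction coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ScreeningThresholds",
    "LMMFit",
    "ScreeningResult",
    "fit_progression_lmm",
    "screen_feature",
    "screen_panel",
    "association_test",
    "select_covariates",
]

REFERENCE_GROUP = "hc"


@dataclass(frozen=True)
class ScreeningThresholds:
    """Flat-HC and progression alpha levels of the screening rule."""

    alpha_hc_flat: float = 0.05
    alpha_progression: float = 0.1

    def __post_init__(self):
        for v in (self.alpha_hc_flat, self.alpha_progression):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class LMMFit:
    feature: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    p_hc_slope: float
    p_interaction: float
    group_slopes: dict      # group -> (estimate, se, p) of the group's own slope
    diff_slopes: dict       # PD group -> (estimate, se, p) vs reference slope
    var_components: dict
    loglike: float
    converged: bool
    random_structure: str   # "intercept+slope" or "intercept"
    n_obs: int
    failure: str | None = None


@dataclass
class ScreeningResult:
    feature: str
    p_hc_slope: float
    p_interaction: float
    p_diff_slopes: dict
    passed: bool
    failure_reason: str | None = None


def _wald_p(est, se):
    se = np.where(np.asarray(se) > 0, se, np.nan)
    z = np.asarray(est) / se
    return 2.0 * stats.norm.sf(np.abs(z))


def _design(data: pd.DataFrame, covariates, groups_order=None):
    """Fixed-effects design shared by every feature in a panel."""
    df = data.copy()
    for c in covariates:
        if pd.api.types.is_numeric_dtype(df[c]):
            df[c] = df[c] - df[c].mean()
    levels = groups_order or [REFERENCE_GROUP] + sorted(
        g for g in df["group"].unique() if g != REFERENCE_GROUP
    )
    df["group"] = pd.Categorical(df["group"], categories=levels)
    terms = list(covariates) + ["group", "visit_time", "group:visit_time"]
    terms += [f"{c}:visit_time" for c in covariates]
    X = dmatrix(" + ".join(terms) if terms else "1", df, return_type="dataframe")
    return df, X


def _fit_mixedlm(y, X, groups, exog_re):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.regression.mixed_linear_model.MixedLM(
            np.asarray(y, float), np.asarray(X, float), groups=np.asarray(groups),
            exog_re=np.asarray(exog_re, float),
        )
        res = model.fit(reml=True, maxiter=300)
    return res


def _extract(feature, res, names, structure) -> LMMFit:
    params = pd.Series(res.fe_params, index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[: len(names), : len(names)],
                       index=names, columns=names)
    with np.errstate(invalid="ignore"):  # degenerate (noise-free) fits
        bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
    pvals = pd.Series(_wald_p(params.values, bse.values), index=names)

    inter = [n for n in names if "group" in n and ":visit_time" in n]
    pd_groups = [n.split("[T.")[1].split("]")[0] for n in inter]
    b = params[inter].values
    C = cov.loc[inter, inter].values
    try:
        w = float(b @ np.linalg.solve(C, b))
        p_omni = float(stats.chi2.sf(w, len(inter)))
    except np.linalg.LinAlgError:
        p_omni = np.nan

    hc_slope = params["visit_time"]
    hc_se = bse["visit_time"]
    diff, slopes = {}, {REFERENCE_GROUP: (hc_slope, hc_se, float(pvals["visit_time"]))}
    for g, n in zip(pd_groups, inter):
        est, se = params[n], bse[n]
        diff[g] = (float(est), float(se), float(pvals[n]))
        # group's own slope = hc slope + differential
        var = cov.loc["visit_time", "visit_time"] + cov.loc[n, n] \
            + 2 * cov.loc["visit_time", n]
        gse = float(np.sqrt(max(var, 0.0)))
        gest = float(hc_slope + est)
        slopes[g] = (gest, gse, float(_wald_p(gest, gse)))

    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    vc = {"sigma2_intercept": float(cov_re[0, 0]),
          "sigma2_residual": float(res.scale)}
    if cov_re.shape[0] > 1:
        vc["sigma2_slope"] = float(cov_re[1, 1])
        vc["cov_intercept_slope"] = float(cov_re[0, 1])
    return LMMFit(
        feature=feature, params=params, bse=bse, pvalues=pvals,
        p_hc_slope=float(pvals["visit_time"]), p_interaction=p_omni,
        group_slopes=slopes, diff_slopes=diff, var_components=vc,
        loglike=float(res.llf), converged=bool(res.converged),
        random_structure=structure, n_obs=int(res.nobs),
    )


def fit_progression_lmm(
    data: pd.DataFrame,
    feature: str,
    covariates=("age",),
) -> LMMFit:
    """Fit the progression-screening LMM for one feature.

    Random intercept + random time slope per subject (unstructured 2x2
    covariance); on convergence failure, refit with a random intercept
    only and flag the fallback in ``random_structure``.
    """
    if data["visit_time"].nunique() < 2:
        raise ValueError("need >= 2 distinct visit times to estimate slopes")
    df, X = _design(data, list(covariates))
    mask = df[feature].notna().to_numpy()
    df, Xv = df.loc[mask], X.loc[mask]
    y = df[feature].to_numpy(float)
    names = list(X.columns)
    Zfull = np.column_stack([np.ones(len(df)), df["visit_time"].to_numpy(float)])
    for structure, Z in (("intercept+slope", Zfull), ("intercept", Zfull[:, :1])):
        try:
            res = _fit_mixedlm(y, Xv, df["subject_id"], Z)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if res.converged or structure == "intercept":
            fit = _extract(feature, res, names, structure)
            if not res.converged:
                fit.failure = "did not converge after fallback"
            return fit
    out = LMMFit(feature, pd.Series(dtype=float), pd.Series(dtype=float),
                 pd.Series(dtype=float), np.nan, np.nan, {}, {}, {}, np.nan,
                 False, "none", int(mask.sum()), failure="singular fit")
    return out


def screen_feature(fit: LMMFit, thresholds: ScreeningThresholds | None = None
                   ) -> ScreeningResult:
    """Apply the flat-HC / PD-progression pass rule to a fitted LMM."""
    th = thresholds or ScreeningThresholds()
    p_diff = {g: v[2] for g, v in fit.diff_slopes.items()}
    if not fit.converged:
        return ScreeningResult(fit.feature, fit.p_hc_slope, fit.p_interaction,
                               p_diff, False, fit.failure or "non-converged fit")
    hc_flat = fit.p_hc_slope > th.alpha_hc_flat
    progresses = (fit.p_interaction < th.alpha_progression) or any(
        p < th.alpha_progression for p in p_diff.values()
    )
    passed = hc_flat and progresses
    reason = None
    if not passed:
        reason = "hc trend not flat" if not hc_flat else "no progression signal"
    return ScreeningResult(fit.feature, fit.p_hc_slope, fit.p_interaction,
                           p_diff, passed, reason)


def screen_panel(
    data: pd.DataFrame,
    features,
    covariates=("age",),
    thresholds: ScreeningThresholds | None = None,
) -> pd.DataFrame:
    """Screen every feature; returns a tidy table, one row per feature.

    Per-feature fit errors are recorded (pass=False) rather than raised.
    The shared fixed-effects design is built once for the whole panel.
    """
    th = thresholds or ScreeningThresholds()
    if data["visit_time"].nunique() < 2:
        raise ValueError("need >= 2 distinct visit times to estimate slopes")
    df, X = _design(data, list(covariates))
    names = list(X.columns)
    Zfull = np.column_stack([np.ones(len(df)), df["visit_time"].to_numpy(float)])
    records = []
    for feat in features:
        mask = df[feat].notna().to_numpy()
        y = df.loc[mask, feat].to_numpy(float)
        fit = None
        for structure, Z in (("intercept+slope", Zfull[mask]),
                             ("intercept", Zfull[mask, :1])):
            try:
                res = _fit_mixedlm(y, X.loc[mask], df.loc[mask, "subject_id"], Z)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged or structure == "intercept":
                fit = _extract(feat, res, names, structure)
                if not res.converged:
                    fit.failure = "did not converge after fallback"
                break
        if fit is None:
            records.append({"feature": feat, "p_hc_slope": np.nan,
                            "p_interaction": np.nan, "passed": False,
                            "failure_reason": "singular fit"})
            continue
        sr = screen_feature(fit, th)
        rec = {"feature": feat, "p_hc_slope": sr.p_hc_slope,
               "p_interaction": sr.p_interaction, "passed": sr.passed,
               "failure_reason": sr.failure_reason}
        for g, p in sr.p_diff_slopes.items():
            rec[f"p_diff_{g}"] = p
        records.append(rec)
    return pd.DataFrame.from_records(records)


def association_test(
    data: pd.DataFrame,
    feature: str,
    clinical_outcome: str = "clinical_score",
    covariates=("age",),
):
    """Association of one feature with the clinical anchor.

    Random-intercept LMM of ``clinical ~ feature + covariates``; returns
    ``(estimate, se, p)`` for the feature coefficient (Wald).
    """
    df = data.loc[data[feature].notna() & data[clinical_outcome].notna()].copy()
    if df[feature].nunique() < 2:
        raise ValueError(f"feature {feature!r} is constant")
    cols = [feature] + list(covariates)
    X = dmatrix(" + ".join(cols), df, return_type="dataframe")
    res = _fit_mixedlm(df[clinical_outcome].to_numpy(float), X,
                       df["subject_id"], np.ones((len(df), 1)))
    names = list(X.columns)
    j = names.index(feature)
    est = float(res.fe_params[j])
    se = float(np.sqrt(np.asarray(res.cov_params())[j, j]))
    return est, se, float(_wald_p(est, se))


def select_covariates(
    data: pd.DataFrame,
    candidate_covariates=("age", "sex"),
    clinical_outcome: str = "clinical_score",
    pd_groups=("de_novo_pd", "mild_moderate_pd", "advanced_pd"),
    alpha: float = 0.05,
) -> list[str]:
    """Keep candidates whose covariate-by-time interaction modifies the
    clinical slope (p < alpha) in the pooled PD subset.

    Each candidate is tested separately with ``clinical ~ covariate +
    time + covariate:time`` and subject random intercept + slope.
    """
    df = data[data["group"].isin(pd_groups)].copy()
    if df.empty:
        raise ValueError("pooled PD subset is empty")
    selected = []
    Z = np.column_stack([np.ones(len(df)), df["visit_time"].to_numpy(float)])
    for cov in candidate_covariates:
        X = dmatrix(f"{cov} + visit_time + {cov}:visit_time", df,
                    return_type="dataframe")
        res = _fit_mixedlm(df[clinical_outcome].to_numpy(float), X,
                           df["subject_id"], Z)
        names = list(X.columns)
        inter = [i for i, n in enumerate(names) if ":" in n]
        b = res.fe_params[inter]
        C = np.asarray(res.cov_params())[np.ix_(inter, inter)]
        w = float(b @ np.linalg.solve(C, b))
        p = float(stats.chi2.sf(w, len(inter)))
        if p < alpha:
            selected.append(cov)
    return selected
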