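"""Composite scoring and the evaluation battery against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from digiprog.evaluate import (
    CompositeModel,
    classify,
    coefficient_of_variation,
    crossvalidated_scores,
    effect_size_slope,
    evaluate_composite,
    fit_composite,
    score,
)
from digiprog.simulate import CohortConfig, feature_names, generate_cohort


def _cohort(seed=0, **kw):
    cfg = CohortConfig(n_per_group=8, n_features=6,
                       progressive_feature_index=(0, 1),
                       skewed_feature_index=(), missing_rate=0.0,
                       outlier_rate=0.0, seed=seed, **kw)
    return generate_cohort(cfg)


def test_perfect_anchor_recovers_feature():
    data = _cohort()
    data["clinical_score"] = data["walk_f000"]
    model = fit_composite(data, ["walk_f000", "sway_f001"], covariates=())
    # standardized-scale coefficient of the anchor feature = its SD
    sd = data["walk_f000"].std(ddof=0)
    assert model.coef["walk_f000"] == pytest.approx(sd, rel=1e-6)
    assert abs(model.coef["sway_f001"]) < 1e-8
    np.testing.assert_allclose(score(model, data), data["clinical_score"],
                               atol=1e-8)


def test_zero_signal_intercept_near_grand_mean():
    data = _cohort(seed=5)
    rng = np.random.default_rng(1)
    data["clinical_score"] = 25 + rng.normal(0, 2, len(data))
    model = fit_composite(data, ["tug_f002"], covariates=())
    se = 2 / np.sqrt(data["subject_id"].nunique())
    assert abs(model.coef["intercept"] - data["clinical_score"].mean()) < 3 * se


def test_refit_deterministic():
    data = _cohort(seed=2)
    m1 = fit_composite(data, feature_names(6)[:3])
    m2 = fit_composite(data, feature_names(6)[:3])
    assert m1.to_json() == m2.to_json()


def test_constant_feature_rejected():
    data = _cohort()
    data["flat"] = 3.0
    with pytest.raises(ValueError, match="constant"):
        fit_composite(data, ["flat"])


def test_score_intercept_only_and_missing_feature():
    model = CompositeModel(features=[], covariates=[], coef={"intercept": 7.5},
                           center={}, scale={})
    rows = _cohort().head(5)
    np.testing.assert_array_equal(score(model, rows), np.full(5, 7.5))
    model2 = CompositeModel(features=["nope"], covariates=[],
                            coef={"intercept": 0, "nope": 1.0},
                            center={"nope": 0}, scale={"nope": 1})
    with pytest.raises(ValueError, match="nope"):
        score(model2, rows)


def test_score_affine_equivariance():
    data = _cohort(seed=3)
    model = fit_composite(data, ["walk_f000"], covariates=())
    shifted = data.copy()
    shifted["walk_f000"] = 3.0 * shifted["walk_f000"] + 10.0
    model_t = CompositeModel(
        features=["walk_f000"], covariates=[], coef=dict(model.coef),
        center={"walk_f000": 3.0 * model.center["walk_f000"] + 10.0},
        scale={"walk_f000": 3.0 * model.scale["walk_f000"]})
    np.testing.assert_allclose(score(model, data), score(model_t, shifted),
                               rtol=1e-10)


def test_cv_scores_noiseless_anchor_and_rmse_oracle():
    data = _cohort(seed=4)
    data["clinical_score"] = 2.0 * data["walk_f000"] + 5.0
    scored = crossvalidated_scores(data, ["walk_f000"], covariates=(),
                                   n_folds=4, seed=0)
    assert scored["composite_score"].notna().all()
    # held-out RMSE ~ 0 for a noiseless single-feature anchor
    err = scored["composite_score"] - scored["clinical_score"]
    assert np.sqrt((err**2).mean()) < 1e-6
    # reported per-group RMSE matches an independent recomputation
    for g, block in scored.groupby("group"):
        manual = float(np.sqrt(np.mean(
            (block["composite_score"] - block["clinical_score"]) ** 2)))
        assert scored.attrs["rmse_by_group"][g] == pytest.approx(manual,
                                                                 abs=1e-10)


def test_cv_scores_same_seed_identical():
    data = _cohort(seed=6)
    s1 = crossvalidated_scores(data, ["walk_f000", "sway_f001"], n_folds=3,
                               seed=9)
    s2 = crossvalidated_scores(data, ["walk_f000", "sway_f001"], n_folds=3,
                               seed=9)
    pd.testing.assert_frame_equal(s1, s2)


def test_no_subject_in_own_training_fold():
    data = _cohort(seed=7)
    data["clinical_score"] = data["walk_f000"] + 100.0
    # leave-fold-out: a subject's score must not depend on its own rows;
    # corrupt one subject and check only that subject's scores move
    scored = crossvalidated_scores(data, ["walk_f000"], covariates=(),
                                   n_folds=4, seed=1)
    victim = data["subject_id"].iloc[0]
    data2 = data.copy()
    data2.loc[data2["subject_id"] == victim, "clinical_score"] += 500.0
    scored2 = crossvalidated_scores(data2, ["walk_f000"], covariates=(),
                                    n_folds=4, seed=1)
    mask = scored["subject_id"] == victim
    np.testing.assert_allclose(scored.loc[mask, "composite_score"],
                               scored2.loc[mask, "composite_score"], rtol=1e-9)


# --- effect size ----------------------------------------------------------

def _slope_table(slopes_by_group):
    rows = []
    i = 0
    for g, slopes in slopes_by_group.items():
        for s in slopes:
            for t in (0.0, 6.0, 12.0):
                rows.append({"subject_id": f"S{i:03d}", "group": g,
                             "visit_time": t, "composite_score": s * t})
            i += 1
    return pd.DataFrame(rows)


def test_effect_size_zero_and_scale_invariance():
    rng = np.random.default_rng(0)
    common = rng.normal(0, 1, 12)
    tab = _slope_table({"de_novo_pd": common, "hc": common})
    d, lo, hi = effect_size_slope(tab, "de_novo_pd")
    assert d == pytest.approx(0.0, abs=1e-12)
    assert lo < 0 < hi
    tab2 = tab.assign(composite_score=2 * tab["composite_score"])
    d2, _, _ = effect_size_slope(tab2, "de_novo_pd")
    assert d2 == pytest.approx(d, abs=1e-12)


def test_effect_size_unit_separation_coverage():
    rng = np.random.default_rng(1)
    cover = 0
    n_sim = 100
    for _ in range(n_sim):
        tab = _slope_table({"de_novo_pd": rng.normal(1, 1, 10),
                            "hc": rng.normal(0, 1, 10)})
        d, lo, hi = effect_size_slope(tab, "de_novo_pd")
        cover += lo <= 1.0 <= hi
    assert cover >= 0.9 * n_sim


def test_effect_size_matches_hand_computation():
    tab = _slope_table({"de_novo_pd": [1.0, 2.0, 3.0], "hc": [0.0, 1.0]})
    d, _, _ = effect_size_slope(tab, "de_novo_pd")
    s1, s0 = np.array([1.0, 2, 3]), np.array([0.0, 1])
    sp = np.sqrt((2 * s1.var(ddof=1) + 1 * s0.var(ddof=1)) / 3)
    assert d == pytest.approx((s1.mean() - s0.mean()) / sp, abs=1e-12)


# --- coefficient of variation --------------------------------------------

def test_cov_within_zero_for_constant_subjects():
    tab = pd.DataFrame({
        "subject_id": np.repeat(["A", "B", "C"], 3),
        "composite_score": np.repeat([10.0, 20.0, 30.0], 3),
    })
    b, w = coefficient_of_variation(tab)
    assert w == 0.0
    assert b > 0


def test_cov_all_identical_both_zero():
    tab = pd.DataFrame({"subject_id": np.repeat(["A", "B"], 4),
                        "composite_score": 5.0})
    b, w = coefficient_of_variation(tab)
    assert b == 0.0 and w == 0.0


def test_cov_matches_anova_oracle():
    # 3 subjects x 3 visits, hand-decomposable one-way layout
    vals = {"A": [10.0, 12.0, 14.0], "B": [20.0, 19.0, 21.0],
            "C": [30.0, 33.0, 27.0]}
    tab = pd.DataFrame({
        "subject_id": np.repeat(list(vals), 3),
        "composite_score": np.concatenate(list(vals.values())),
    })
    y = tab["composite_score"].to_numpy()
    grand = y.mean()
    means = np.array([np.mean(v) for v in vals.values()])
    ssb = 3 * np.sum((means - grand) ** 2)
    ssw = sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in vals.values())
    msb, msw = ssb / 2, ssw / 6
    sigma_b = np.sqrt((msb - msw) / 3)
    b, w = coefficient_of_variation(tab)
    assert b == pytest.approx(sigma_b / grand, abs=1e-12)
    assert w == pytest.approx(np.sqrt(msw) / grand, abs=1e-12)


def test_cov_nonpositive_mean_errors():
    tab = pd.DataFrame({"subject_id": np.repeat(["A", "B"], 3),
                        "composite_score": -1.0})
    with pytest.raises(ValueError, match="grand mean"):
        coefficient_of_variation(tab)


# --- classification -------------------------------------------------------

def _scored_two_groups(pos, neg):
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(len(pos) + len(neg))],
        "group": ["de_novo_pd"] * len(pos) + ["hc"] * len(neg),
        "composite_score": list(pos) + list(neg),
    })


def test_perfect_separation():
    tab = _scored_two_groups([5.0, 6, 7], [1.0, 2, 3])
    auc, thr, conf = classify(tab)
    assert auc == 1.0
    assert conf["fp"] == conf["fn"] == 0
    assert 3 < thr <= 5


def test_auc_equals_pairwise_concordance_count():
    rng = np.random.default_rng(2)
    pos = rng.normal(1, 1, 5)
    neg = rng.normal(0, 1, 5)
    auc, _, _ = classify(_scored_two_groups(pos, neg))
    brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
    assert auc == pytest.approx(brute, abs=1e-12)


def test_auc_null_near_half():
    rng = np.random.default_rng(3)
    auc, _, _ = classify(_scored_two_groups(rng.normal(size=500),
                                            rng.normal(size=500)))
    assert abs(auc - 0.5) < 0.05


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
    a1, _, _ = classify(_scored_two_groups(pos, neg))
    a2, _, _ = classify(_scored_two_groups(np.exp(pos), np.exp(neg)))
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_one_class_errors():
    tab = _scored_two_groups([1.0, 2.0], [])
    with pytest.raises(ValueError):
        classify(tab)


def test_evaluate_composite_report_roundtrip():
    data = _cohort(seed=11)
    scored = crossvalidated_scores(data, feature_names(6)[:2], n_folds=3,
                                   seed=0)
    report = evaluate_composite(scored)
    blob = report.to_json()
    assert '"auc"' in blob
    assert 0.0 <= report.auc <= 1.0
    assert report.between_cov >= 0 and report.within_cov >= 0
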