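# Methods

`digiprog` implements a complete workflow for building a *composite digital
biomarker* of disease progression from a high-dimensional panel of
longitudinal sensor-derived features, anchored to a clinician-rated score
(an MDS-UPDRS-Part-III-like scale). This note documents the statistical
models, the algorithmic and numerical choices, and what the synthetic
cohort generator does and does not emulate.

## Study design and the synthetic cohort generator

The workflow assumes an observational design with four groups — de novo
PD, mild-to-moderate PD (on therapy), advanced PD, and healthy controls
(HC) — assessed once every 3 months for 2 years (visit times 0, 3, …, 24
months). The default cohort size is 10 subjects per group, matching that
design; operating-characteristic checks use 20 per group.

Each digital feature k for subject j in group g follows a linear
mixed-effects trajectory

    y_jk(t) = mu_gk + b0_jk + (s_gk + b1_jk) t + eps_jk(t),

with independent subject-level random intercepts `b0 ~ N(0, 0.5^2)` and
random slopes `b1 ~ N(0, 0.05^2)` per feature, residual noise
`eps ~ N(0, 0.5^2)`, slopes `s_gk` in feature units/month, and group
baseline offsets `mu_gk`. Defaults encode the qualitative pattern the
design targets: progression in de novo (0.12/month) and advanced PD
(0.10/month) on the progressive feature subset, flat trajectories in the
treated mild-to-moderate group and in HC, and baseline elevation of all
PD groups (1.0 / 0.5 / 1.5 units). With the default random-slope SD this
gives standardized slope differences (Cohen's d on subject slopes) of
roughly 2 for de novo vs HC — comparable to the effect sizes such
composite measures report.

Further structure:

- **Cross-feature correlation** is induced block-wise (default block size
  5, target residual correlation 0.3) through shared Gaussian latent
  factors added to the residuals. Sensor feature panels carry unknown
  redundancies and covariances; a latent-factor block model is the
  simplest controllable emulation.
- **Skewness**: designated features are generated on the log scale and
  exponentiated, so they are strictly positive and right-skewed; the QC
  stage is expected to log them back.
- **Missingness** is MCAR at a configurable cell rate (default 5%) —
  mean imputation, which the QC stage uses, is only defensible under
  MCAR, so the generator does not model informative missingness.
- **Outliers**: cells are displaced by ±8 residual SDs at rate 0.5%.
- **Clinical anchor**: `anchor = 5 + 10 * (mean noise-free progressive
  signal) + N(0, 3^2)`, left continuous (integer rounding is a config
  flag). The anchor is driven by the latent progression signal, not by
  the noisy observed features, so feature noise attenuates the
  feature–anchor association exactly as measurement error would.
- **Covariates**: age is drawn per group from normal distributions with
  means 66.2/61.6/71.2/65.6 years (SDs 6.46/10.76/4.78/6.98); sex is
  Bernoulli with male proportions 0.5/0.9/0.5/0.3.

What the generator does **not** emulate: biomechanical realism of gait or
sway, floor/ceiling effects, informative missingness, visit-time jitter,
practice effects, and medication-state fluctuations. Tests passing on
these cohorts demonstrate that the *statistical machinery* behaves as
designed under the assumed data-generating process; they are not evidence
about any particular sensor system.

An epoch-level generator draws `epochs_per_task` values around each
subject-visit feature value so the aggregation stage (mean, median, SD,
mean absolute deviation about the mean) can be exercised end to end.

## Quality control

Pipeline order is fixed: aggregate epochs → remove non-informative
features → mean-impute → prune correlated features → log-transform skewed
features → remove per-value outliers → re-impute. The stage is idempotent
on its own output. Thresholds are configuration with defaults chosen as
conventional values, all logged and overridable:

| parameter | default | meaning |
|---|---|---|
| `min_distinct_values` | 5 | fewer distinct observed values → non-informative |
| `max_missing_fraction` | 0.5 | heavier missingness → removed |
| `extreme_value_rule` | 6 | any |robust z| (median/1.4826·MAD) beyond → removed; judged on the log scale for strictly positive features whose skewness already exceeds `skew_threshold`, since those are destined for the log-transform step and a raw-scale z would misread the long tail |
| `corr_threshold` | 0.95 | pairwise |r| beyond → later feature pruned |
| `skew_threshold` | 2.0 | adjusted Fisher–Pearson skewness beyond → log |
| `outlier_winsor_z` | 4 | per-value robust z beyond → value blanked, re-imputed |

Correlation pruning is greedy in descending-variance order (ties broken
by name), keeping the higher-variance member of a correlated pair —
deterministic, and variance is a crude proxy for retained information.
Outlier handling removes individual values rather than whole visits so
the longitudinal grid is preserved.

## Univariate progression screening

Each feature is screened with the LMM

    feature ~ covariates + group + time + group:time + covariate:time
              + (1 + time | subject),

REML, continuous time in months, HC as the reference group level, and
covariates mean-centered so the `time` main effect is the HC slope at the
average covariate value. The random intercept+slope covariance is
unstructured; if that fit fails, the model falls back to a random
intercept only and the fallback is flagged. All p-values are Wald tests
on the normal approximation; the omnibus group-by-time test is a
3-degree-of-freedom Wald chi-square over the interaction coefficients
(the natural multi-group generalization of a single "interaction
p-value").

A feature passes when (1) its HC trend is flat, `p_HC > 0.05`, and (2) it
progresses in PD, `p_omnibus < 0.1` **or** any PD-vs-HC differential
slope p < 0.1. No multiplicity correction is applied at screening — the
thresholds are deliberately relaxed to retain candidates. A consequence
worth knowing: under the global null the pass rule fires at rate ≈ 0.21
(the union of four correlated level-0.1 tests times the 0.95 flat-HC
factor), so the screen's specificity is by construction about 0.79–0.80.

Covariate selection fits `clinical ~ covariate + time + covariate:time`
with random intercept and slope on the pooled PD subset and keeps
covariates whose interaction p < 0.05. The association step fits
`clinical ~ feature + covariates` with a subject random intercept; it is
reported but (matching the relaxed-screening philosophy) not used to drop
features by default.

## GEE and SCAD-penalized GEE

The core estimator solves the generalized estimating equations
`sum_i D_i' V_i^{-1} (y_i − mu_i) = 0` by Fisher scoring with moment
re-estimation of the working correlation each sweep (exchangeable and
AR-1 estimators clipped to ±0.99), identity link for the continuous
endpoint and logit for the binary endpoint, and reports both model-based
and robust (sandwich) covariances. Equal-size clusters are processed in
batched einsum form, using the identity that both links reduce to
`U_i' R^{-1} U_i / phi` with `U_i = A_i^{1/2} X_i` and Pearson residuals.

Penalized GEE augments the estimating function with the SCAD penalty
derivative

    q_lambda(theta) = lambda                     for theta <= lambda
                    = (a·lambda − theta)_+/(a−1) for theta >  lambda,

a = 3.7, and iterates the local quadratic approximation

    beta ← beta + [H + n·E]^{-1} [S − n·E·beta],
    E_jj = q_lambda(|beta_j|) / (eps_ridge + |beta_j|)  (penalized j only),

with `eps_ridge = 1e-6`, convergence at max|update| < 1e-6 or 200
iterations, and a Newton step capped at inf-norm 5 so that
quasi-separated logistic fits drift to saturation instead of overflowing.
Two scaling choices matter and are deliberate:

- **Penalty multiplier n** is the total observation count, matching the
  `n · p_lambda` scaling of penalized likelihood in which the information
  H also scales with observations. This keeps the effective selection
  threshold on a standardized coefficient at ≈ lambda regardless of
  cluster size, which is what makes a single lambda grid meaningful.
- **Standardization**: penalized columns are standardized to training
  mean 0 / SD 1 inside the fit; coefficients are reported on the
  standardized scale (with a back-transformed copy), because both the
  penalty and ranking by estimate magnitude are meaningless across
  heterogeneous feature units.

A coefficient is "selected" when its standardized magnitude exceeds
`zero_cutoff = 1e-3`. The intercept and covariates are never penalized.

**Penalty-level tuning** is cluster-held-out cross-validation (default 4
folds, grid 0.01–1.0) with the **one-standard-error rule**: the largest
lambda whose mean held-out loss (MSE or deviance) is within one SE of the
minimum. The parsimony rule is not cosmetic here: the local quadratic
approximation leaves O(SE)-sized residues on noise coefficients at the
loss-minimizing lambda, so minimum-CV selection keeps spurious features;
the 1-SE choice restores exact-support recovery (verified at ≥ 80% over
replicates in the acceptance battery). `rule="min"` is available.

## Feature-count selection and merging

Candidates are ranked by descending |standardized PGEE estimate| (zeros
dropped, ties by name). The number of top features P is chosen by
subject-level, group-stratified K-fold CV (default 5 folds for selection):
within each training fold a PGEE is fit and features re-ranked — the
stricter reading of "ranked from the training set" — then for each k an
*unpenalized* GEE on the top-k features is scored on held-out subjects:
RMSE (minimized) for the continuous endpoint, AUC (maximized) for the
binary de-novo-vs-HC endpoint; ties go to smaller k. The refit is
unpenalized so the curve reflects the feature set, not shrinkage. Lambda
is tuned once on the full data and shared across folds (no nested
tuning). The progression and classification feature sets are merged by
order-preserving union, duplicates counted once.

## Composite construction and evaluation

The composite digital measure is the linear predictor of a gaussian GEE
(exchangeable working correlation) of the clinical anchor on the merged,
standardized feature set plus covariates; the model stores its
standardization parameters so scoring is self-contained. Covariate terms
are included in the score by default (a covariate-free scoring flag
exists). Evaluation is on 10-fold subject-level cross-validated scores —
each subject scored by a model that never saw it:

- **Progression**: the screening LMM refit with the composite as the
  response (age-adjusted): omnibus group-by-time p, HC slope p, and
  per-PD-group differential slope p.
- **Effect sizes**: Cohen's d between per-subject OLS slopes of the
  composite (PD group vs HC), pooled-SD denominator, 95% CI from the
  large-sample SE of d. This definition is an explicit choice; published
  tables rarely state theirs, so no numerical equivalence with any
  specific report is claimed.
- **Variability**: between- and within-subject coefficients of variation
  from a one-way method-of-moments variance decomposition of the score by
  subject (unbalanced n0 coefficient; negative between-components clipped
  at 0), divided by the grand mean. The grand mean must be positive;
  scores are never re-centered silently.
- **Classification** (de novo PD vs HC): Mann–Whitney AUC over pooled
  subject-visit scores, threshold maximizing Youden's J (ties toward the
  lower threshold), confusion counts at that threshold.

## Problem sizes used in tests

The acceptance battery runs at deliberately modest sizes chosen as the
package's own verification scale: support recovery at 100 clusters × 4
visits × 50 features over 50 replicates; screening operating
characteristics on one 200-feature panel (50 progressive) and one
500-feature null panel at 20 subjects/group; feature-count CV and the
end-to-end pattern over 25 seeds. The end-to-end check asserts the
qualitative pattern the design encodes — flat HC and mild-moderate,
progressing de novo and advanced, AUC > 0.9 — not any dataset-specific
numbers, which are not reproducible without the original study data.

## Known limitations

- Wald-normal p-values are mildly anti-conservative at 10 subjects/group;
  no Satterthwaite or Kenward–Roger correction is implemented.
- The LQA never produces exact zeros; selection relies on the 1e-3
  cutoff on the standardized scale.
- Mean imputation understates uncertainty; no model-based imputation.
- The screening step's ≈ 0.79 null specificity is a property of the
  published pass rule, not of this implementation.
- Binary-endpoint GEE under complete separation reports a non-converged
  fit with saturated probabilities; coefficients are then not
  interpretable even though CV losses and rankings remain usable.
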