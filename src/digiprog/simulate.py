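"""Synthetic longitudinal cohorts with the structure the framework assumes.

The generator emulates a four-group observational study (de novo PD,
mild-to-moderate PD on therapy, advanced PD, healthy controls) with clinic
visits every 3 months for 2 years.  Each digital feature follows a linear
mixed-effects trajectory within subject,

    feature_k(t) = mu_gk + b0_jk + (s_gk + b1_jk) * t + eps_ijk,

with subject-level random intercepts ``b0 ~ N(0, sigma_int^2)`` and random
slopes ``b1 ~ N(0, sigma_slope^2)`` drawn independently per feature, and
residual noise ``eps ~ N(0, sigma_res^2)``.  Cross-feature correlation is
induced block-wise through shared Gaussian latent factors added to the
residuals; designated features are generated on the log scale and
exponentiated (right skew); missing cells are MCAR; occasional outliers are
injected.  A continuous clinical anchor score (an MDS-UPDRS-III-like scale)
is an affine function of the noise-free progressive signal plus Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "CohortConfig",
    "generate_cohort",
    "generate_epoch_table",
    "feature_names",
]

GROUPS = ("de_novo_pd", "mild_moderate_pd", "advanced_pd", "hc")

#: per-group age mean/SD (years) and male proportion for the default cohort
_AGE_MODEL = {
    "de_novo_pd": (66.2, 6.46),
    "mild_moderate_pd": (61.6, 10.76),
    "advanced_pd": (71.2, 4.78),
    "hc": (65.6, 6.98),
}
_MALE_PROP = {
    "de_novo_pd": 0.5,
    "mild_moderate_pd": 0.9,
    "advanced_pd": 0.5,
    "hc": 0.3,
}

_TASKS = ("walk", "sway", "tug")


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Slopes are in feature units per month; visit times in months.  Group
    slope defaults encode the qualitative pattern of the target study
    design: progression in the de novo and advanced PD groups, a flat
    trajectory in the treated mild-to-moderate group and in healthy
    controls.
    """

    n_per_group: int = 10
    groups: Sequence[str] = GROUPS
    visit_times: Sequence[float] = tuple(range(0, 25, 3))
    n_features: int = 20
    progressive_feature_index: Sequence[int] | None = None  # default: first 5
    group_slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "de_novo_pd": 0.12,
            "mild_moderate_pd": 0.0,
            "advanced_pd": 0.10,
            "hc": 0.0,
        }
    )
    group_baseline: Mapping[str, float] = field(
        default_factory=lambda: {
            "de_novo_pd": 1.0,
            "mild_moderate_pd": 0.5,
            "advanced_pd": 1.5,
            "hc": 0.0,
        }
    )
    random_intercept_sd: float = 0.5
    random_slope_sd: float = 0.05
    residual_sd: float = 0.5
    feature_corr: float = 0.3
    corr_block_size: int = 5
    skewed_feature_index: Sequence[int] | None = None       # default: last 5
    skew_strength: float = 1.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.005
    outlier_scale: float = 8.0
    anchor_weights: Sequence[float] | None = None
    anchor_offset: float = 5.0
    anchor_scale: float = 10.0
    anchor_noise_sd: float = 3.0
    round_anchor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.progressive_feature_index is None:
            self.progressive_feature_index = tuple(
                range(min(5, self.n_features)))
        if self.skewed_feature_index is None:
            low = max(self.n_features - 5, max(
                (int(i) + 1 for i in self.progressive_feature_index),
                default=0))
            self.skewed_feature_index = tuple(range(low, self.n_features))
        for name in ("groups", "visit_times", "progressive_feature_index",
                     "skewed_feature_index"):
            setattr(self, name, tuple(getattr(self, name)))
        if self.anchor_weights is not None:
            self.anchor_weights = tuple(self.anchor_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        vt = np.asarray(self.visit_times, dtype=float)
        if vt.size < 1 or np.any(np.diff(vt) <= 0):
            raise ConfigError("visit_times must be non-empty and strictly increasing")
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd",
                     "anchor_noise_sd", "skew_strength", "outlier_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1)")
        if not (0 <= self.feature_corr < 1):
            raise ConfigError("feature_corr must be in [0, 1)")
        bad = [i for i in self.progressive_feature_index
               if not (0 <= int(i) < self.n_features)]
        if bad:
            raise ConfigError(f"progressive_feature_index out of range: {bad}")
        bad = [i for i in self.skewed_feature_index
               if not (0 <= int(i) < self.n_features)]
        if bad:
            raise ConfigError(f"skewed_feature_index out of range: {bad}")
        for g in self.groups:
            if g not in self.group_slopes:
                raise ConfigError(f"group_slopes missing group {g!r}")
        if self.anchor_weights is not None and len(self.anchor_weights) != len(
            self.progressive_feature_index
        ):
            raise ConfigError("anchor_weights must match progressive_feature_index")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, dict):
                d[k] = dict(v)
        return d

    def save(self, path: str) -> None:
        d = self.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(d, fh)
            else:
                json.dump(d, fh, indent=2, default=list)

    @classmethod
    def load(cls, path: str) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            if str(path).endswith((".yaml", ".yml")):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls(**d)


def feature_names(n_features: int) -> list[str]:
    """Task-prefixed feature names, tasks assigned round-robin."""
    return [f"{_TASKS[k % len(_TASKS)]}_f{k:03d}" for k in range(n_features)]


def _slope_matrix(config: CohortConfig) -> np.ndarray:
    """Group-by-feature true slope matrix (units/month)."""
    s = np.zeros((len(config.groups), config.n_features))
    prog = np.asarray(config.progressive_feature_index, dtype=int)
    for gi, g in enumerate(config.groups):
        s[gi, prog] = float(config.group_slopes[g])
    return s


def _baseline_matrix(config: CohortConfig) -> np.ndarray:
    mu = np.zeros((len(config.groups), config.n_features))
    prog = np.asarray(config.progressive_feature_index, dtype=int)
    for gi, g in enumerate(config.groups):
        mu[gi, prog] = float(config.group_baseline.get(g, 0.0))
    return mu


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a long-format subject-visit table.

    Returns one row per (subject, visit) with columns ``subject_id``,
    ``group``, ``visit_time``, ``age``, ``sex``, ``clinical_score`` and one
    column per digital feature.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = list(config.groups)
    n_g, n_sub = len(groups), len(groups) * config.n_per_group
    t = np.asarray(config.visit_times, dtype=float)
    n_vis, n_feat = t.size, config.n_features
    names = feature_names(n_feat)

    mu = _baseline_matrix(config)
    slopes = _slope_matrix(config)
    prog = np.asarray(config.progressive_feature_index, dtype=int)
    if config.anchor_weights is None:
        w = np.full(prog.size, 1.0 / max(prog.size, 1))
    else:
        w = np.asarray(config.anchor_weights, dtype=float)

    group_of = np.repeat(np.arange(n_g), config.n_per_group)
    b0 = rng.normal(0.0, config.random_intercept_sd, (n_sub, n_feat))
    b1 = rng.normal(0.0, config.random_slope_sd, (n_sub, n_feat))

    # residuals with block correlation via shared latent factors
    rho = config.feature_corr
    eps = np.sqrt(1.0 - rho) * rng.standard_normal((n_sub, n_vis, n_feat))
    if rho > 0:
        n_blocks = int(np.ceil(n_feat / config.corr_block_size))
        latent = rng.standard_normal((n_sub, n_vis, n_blocks))
        block_of = np.arange(n_feat) // config.corr_block_size
        eps += np.sqrt(rho) * latent[:, :, block_of]
    eps *= config.residual_sd

    # signal: (n_sub, n_vis, n_feat)
    signal = (
        mu[group_of][:, None, :]
        + b0[:, None, :]
        + (slopes[group_of][:, None, :] + b1[:, None, :]) * t[None, :, None]
    )
    values = signal + eps

    # anchor from the noise-free progressive signal
    anchor_signal = signal[:, :, prog] @ w if prog.size else np.zeros((n_sub, n_vis))
    anchor = (
        config.anchor_offset
        + config.anchor_scale * anchor_signal
        + rng.normal(0.0, config.anchor_noise_sd, (n_sub, n_vis))
    )
    if config.round_anchor:
        anchor = np.rint(anchor)

    # outliers, then MCAR missingness (order fixed so rates are marginal)
    if config.outlier_rate > 0:
        mask = rng.random(values.shape) < config.outlier_rate
        shift = config.outlier_scale * config.residual_sd
        values = values + mask * shift * np.sign(rng.standard_normal(values.shape))
    skew = np.asarray(config.skewed_feature_index, dtype=int)
    if skew.size:
        values[:, :, skew] = np.exp(config.skew_strength * values[:, :, skew])
    if config.missing_rate > 0:
        values[rng.random(values.shape) < config.missing_rate] = np.nan

    age = np.empty(n_sub)
    sex = np.empty(n_sub, dtype=object)
    for j in range(n_sub):
        g = groups[group_of[j]]
        m, s = _AGE_MODEL.get(g, (65.0, 7.0))
        age[j] = rng.normal(m, s)
        sex[j] = "M" if rng.random() < _MALE_PROP.get(g, 0.5) else "F"

    rows = {
        "subject_id": np.repeat([f"S{j:03d}" for j in range(n_sub)], n_vis),
        "group": np.repeat([groups[g] for g in group_of], n_vis),
        "visit_time": np.tile(t, n_sub),
        "age": np.repeat(age, n_vis),
        "sex": np.repeat(sex, n_vis),
        "clinical_score": anchor.ravel(),
    }
    df = pd.DataFrame(rows)
    flat = values.reshape(n_sub * n_vis, n_feat)
    for k, name in enumerate(names):
        df[name] = flat[:, k]
    return df


def generate_epoch_table(
    config: CohortConfig,
    epochs_per_task: int,
    dispersion: float = 1.0,
) -> pd.DataFrame:
    """Epoch-level draws around each subject-visit feature value.

    One row per (subject, visit, task, feature, epoch); epoch values are
    ``N(subject-visit value, dispersion^2)`` so that the epoch mean recovers
    the subject-visit value up to sampling error.  The companion cohort is
    generated with ``missing_rate=0`` and ``outlier_rate=0`` so every cell
    has a defined target.
    """
    if epochs_per_task < 1:
        raise ConfigError("epochs_per_task must be >= 1")
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    base_cfg = CohortConfig(**{**config.to_dict(), "missing_rate": 0.0,
                               "outlier_rate": 0.0})
    cohort = generate_cohort(base_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    names = feature_names(config.n_features)
    task_of = {name: name.split("_")[0] for name in names}

    n_rows = len(cohort)
    n_feat = len(names)
    target = cohort[names].to_numpy()  # (n_rows, n_feat)
    draws = target[:, :, None] + dispersion * rng.standard_normal(
        (n_rows, n_feat, epochs_per_task)
    )
    rec = {
        "subject_id": np.repeat(cohort["subject_id"].to_numpy(), n_feat * epochs_per_task),
        "visit_time": np.repeat(cohort["visit_time"].to_numpy(), n_feat * epochs_per_task),
        "task": np.tile(np.repeat([task_of[n] for n in names], epochs_per_task), n_rows),
        "feature_name": np.tile(np.repeat(names, epochs_per_task), n_rows),
        "epoch_index": np.tile(np.arange(1, epochs_per_task + 1), n_rows * n_feat),
        "value": draws.ravel(),
    }
    return pd.DataFrame(rec)
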