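import warnings

import numpy as np
import pytest

from digiprog import CohortConfig, generate_cohort

# MixedLM emits convergence chatter on boundary variance fits; the fits
# themselves are checked through their returned flags.
warnings.filterwarnings("ignore", message=".*converge.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with no missingness/outliers/skew: convenient for
    model-recovery tests."""
    cfg = CohortConfig(n_per_group=10, n_features=8,
                       progressive_feature_index=(0, 1, 2),
                       skewed_feature_index=(), missing_rate=0.0,
                       outlier_rate=0.0, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise cohort: every feature exactly linear in time."""
    cfg = CohortConfig(n_per_group=3, n_features=6,
                       progressive_feature_index=(0, 1),
                       random_intercept_sd=0.0, random_slope_sd=0.0,
                       residual_sd=0.0, feature_corr=0.0,
                       skewed_feature_index=(), missing_rate=0.0,
                       outlier_rate=0.0, anchor_noise_sd=0.0, seed=5)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
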