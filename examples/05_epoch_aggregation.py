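"""Aggregate epoch-level task data into subject-visit features.

Sensor software emits one row per step / turn / sway epoch within a
task; the analysis works on task-level summaries. This script generates
an epoch table around a known cohort, aggregates with the four summary
statistics (mean, median, SD, mean absolute deviation about the mean),
and shows the epoch mean recovering the underlying subject-visit value.
"""

import numpy as np

from digiprog import CohortConfig, generate_cohort, generate_epoch_table
from digiprog.preprocess import aggregate_epochs

cfg = CohortConfig(n_per_group=2, n_features=3, visit_times=(0, 12, 24),
                   skewed_feature_index=(), missing_rate=0.0,
                   outlier_rate=0.0, seed=3)
epochs = generate_epoch_table(cfg, epochs_per_task=50, dispersion=1.0)
print(f"epoch table: {len(epochs)} rows "
      f"({epochs['epoch_index'].max()} epochs per subject-visit-feature)")
print(epochs.head(3).to_string(index=False), "\n")

agg = aggregate_epochs(epochs, ("mean", "median", "sd", "mad"))
print("aggregated columns:", [c for c in agg.columns if "__" in c], "\n")

truth = generate_cohort(CohortConfig(**{**cfg.to_dict()}))
merged = truth.merge(agg, on=["subject_id", "visit_time"])
err = merged["walk_f000__mean"] - merged["walk_f000"]
print(f"epoch-mean vs true subject-visit value: max |error| = "
      f"{np.abs(err).max():.3f} (sampling error ~ 1/sqrt(50) = 0.14)")
print(f"mean aggregated SD = {merged['walk_f000__sd'].mean():.3f} "
      f"(epoch dispersion was 1.0)")
print("\nWith 50 epochs the mean tracks the latent value to ~0.14 and the "
      "SD estimates the epoch dispersion; downstream QC treats each "
      "(feature, statistic) pair as its own digital feature.")
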