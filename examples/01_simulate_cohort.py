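"""Generate a synthetic longitudinal cohort and inspect its structure.

Builds the default study design — 4 groups (de novo PD, mild-to-moderate
PD, advanced PD, healthy controls) x 10 subjects x 9 visits over 2 years
— and prints group-level summaries of the clinical anchor and one
progressive digital feature.
"""

import numpy as np

from digiprog import CohortConfig, generate_cohort

cfg = CohortConfig(seed=7)
data = generate_cohort(cfg)

print(f"cohort: {len(data)} subject-visits, "
      f"{data['subject_id'].nunique()} subjects, "
      f"{cfg.n_features} digital features\n")

print("mean clinical anchor score by group and visit (months):")
table = data.pivot_table(values="clinical_score", index="group",
                         columns="visit_time", aggfunc="mean").round(1)
print(table, "\n")

feat = "walk_f000"  # a truly progressive feature
print(f"per-group mean subject slope of {feat} (units/month):")
for g, block in data.groupby("group"):
    slopes = [np.polyfit(b["visit_time"], b[feat].ffill().bfill(), 1)[0]
              for _, b in block.groupby("subject_id")]
    print(f"  {g:18s} {np.mean(slopes):+.3f}   (true {cfg.group_slopes[g]:+.2f})")
print("\nRising anchor means in de novo/advanced PD and near-zero HC "
      "slopes reflect the progression structure the generator encodes.")
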