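"""SCAD-penalized GEE: simultaneous estimation and variable selection.

Simulates clustered longitudinal data with 5 true effects among 50
features, tunes the penalty level by cluster-held-out cross-validation
(one-standard-error rule), and shows that the selected support matches
the truth while an unpenalized GEE keeps everything.
"""

import numpy as np

from digiprog import fit_gee, fit_pgee, tune_lambda

rng = np.random.default_rng(3)
n_clusters, size, p = 100, 4, 50
beta = np.zeros(p + 1)
beta[1:6] = 0.8                       # features 1..5 are real
X = np.column_stack([np.ones(n_clusters * size),
                     rng.standard_normal((n_clusters * size, p))])
subject_effect = rng.normal(0, np.sqrt(0.3), n_clusters)
noise = rng.normal(0, np.sqrt(0.7), (n_clusters, size))
y = X @ beta + (subject_effect[:, None] + noise).ravel()
clusters = np.repeat(np.arange(n_clusters), size)

lam, losses = tune_lambda(X, y, clusters, corstr="exchangeable", seed=0)
fit = fit_pgee(X, y, clusters, corstr="exchangeable", lam=lam)
plain = fit_gee(X, y, clusters, corstr="exchangeable")

print(f"CV-tuned lambda: {lam}")
print(f"true support:      {sorted(range(1, 6))}")
print(f"PGEE support:      {sorted(fit.support)}")
print(f"PGEE estimates on support (standardized): "
      f"{np.round(fit.params[fit.support], 3)}")
print(f"unpenalized GEE |coef| > 0.05: "
      f"{int(np.sum(np.abs(plain.params[1:]) > 0.05))} of {p} features")
print(f"\nexchangeable correlation estimate: {fit.corr.alpha:.3f} (true 0.3)")
print("SCAD keeps the 5 real coefficients nearly unbiased (~0.8 each) "
      "while zeroing the 45 noise features that plain GEE cannot.")
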