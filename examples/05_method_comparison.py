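"""Method-comparison statistics: Passing-Bablok and correlated AUCs.

Two 'measurement methods' read the same underlying quantity with
different scale and noise; Passing-Bablok recovers the structural
relation without assuming error-free x.  The same subjects' scores then
feed the Hanley-McNeil test of two correlated AUCs.
"""

import numpy as np

from ccmorph.stats import paired_auc_test, passing_bablok

rng = np.random.default_rng(3)

# method B reads 1.15 * A + 40 with independent noise on both
truth = rng.uniform(100, 400, size=40)
method_a = truth + rng.normal(0, 10, size=40)
method_b = 1.15 * truth + 40 + rng.normal(0, 10, size=40)

fit = passing_bablok(method_a, method_b)
print(f"Passing-Bablok: slope {fit.slope:.3f} "
      f"(95% CI {fit.slope_ci[0]:.3f}-{fit.slope_ci[1]:.3f}), "
      f"intercept {fit.intercept:.1f} "
      f"(95% CI {fit.intercept_ci[0]:.1f}-{fit.intercept_ci[1]:.1f})")

# correlated-AUC comparison: two endpoints on the same subjects
n = 25
labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
disease = np.concatenate([rng.normal(-1.2, 1, n), rng.normal(0, 1, n)])
v1 = disease + rng.normal(0, 0.5, 2 * n)
v2 = disease + rng.normal(0, 0.9, 2 * n)
z, p, r1, r2 = paired_auc_test(v1, v2, labels, direction="lower")
print(f"AUC1 {r1.auc:.3f} +/- {r1.se_auc:.3f}, "
      f"AUC2 {r2.auc:.3f} +/- {r2.se_auc:.3f}, z = {z:.2f}, p = {p:.3f}")

# The CI on the slope should cover 1.15 and exclude 1 (proportional
# bias); the AUC z-test accounts for the correlation induced by scoring
# the same subjects twice, as a paired t-test would.
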