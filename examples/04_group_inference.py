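"""Two-group comparison of Cp AUC with an injected clustering effect.

Generates a 12+12 cohort where smokers get +0.2 within-module
correlation, sweeps Cp over the sparsity grid, and compares the AUC
between groups with a pooled two-sample t-test; then correlates the
smokers' modular coherence with their age of first smoking (coupled at
r = 0.35 by the generator's Gaussian copula).
"""

import numpy as np

from wmconn import (
    SyntheticCohortSpec,
    binarize_at_sparsity,
    clinical_correlation,
    correlation_matrix,
    default_sparsity_grid,
    make_cohort_connectomes,
    two_sample_t,
)
from wmconn.metrics import auc_trapezoid, cp_lp

grid = default_sparsity_grid()
spec = SyntheticCohortSpec(
    n_per_group=12, n_nodes=32, effect=0.2, clinical_r=0.35, seed=5
)
cohort = make_cohort_connectomes(spec)

auc = {"smoker": [], "control": []}
for ts, grp in zip(cohort.series, cohort.groups):
    conn = correlation_matrix(ts)
    cps = np.array([cp_lp(binarize_at_sparsity(conn, float(s)))[0] for s in grid])
    auc[grp].append(auc_trapezoid(grid, cps))

t, p = two_sample_t(auc["smoker"], auc["control"])
print(f"Cp AUC: smokers {np.mean(auc['smoker']):.4f} "
      f"vs controls {np.mean(auc['control']):.4f}")
print(f"pooled t = {t:.3f}, two-sided p = {p:.4f} "
      f"(positive t: smokers higher, as injected)")

onset = cohort.clinical.query("group == 'smoker'")["onset_age"].to_numpy()
res = clinical_correlation(cohort.coherence[:12], onset)
print(f"coherence vs onset age: Pearson r = {res.r:.3f} (target 0.35), "
      f"p = {res.p:.3f}, n = {res.n}")
# at n = 12 the correlation estimate is noisy; the recovery tests average
# many replicates at n = 42 to show the copula target is unbiased
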