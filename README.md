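# wmconn

White-matter (WM) functional connectome construction and graph-theoretical
analysis for resting-state fMRI, with seeded synthetic generators for every
input so the whole pipeline is testable on a desk without any imaging data.

BOLD fluctuations in white matter carry organized, behaviourally relevant
signal, and networks built from inter-parcel WM correlations show
small-world topology that is altered in clinical groups (including young
smokers, the cohort this pipeline is modelled on). `wmconn` implements the
full analysis chain such a study needs:

1. **Masking** — threshold each subject's WM tissue-probability map at a
   strict 90% rule, intersect subjects with an at-least-80% overlap rule,
   and strip subcortical grey nuclei via a label volume.
2. **Parcellation** — randomly subdivide the group WM mask into *N*
   contiguous, size-balanced nodes (default *N* = 128) by region growing:
   random seed voxels, then always grow the currently smallest parcel.
3. **Signal cleaning** — drop initial volumes, scrub frames with framewise
   displacement FD > 0.5 mm (plus one forward and two back neighbours),
   linear detrend and 0.01–0.10 Hz bandpass; no spatial smoothing.
4. **Connectome** — parcel-averaged time series, Pearson correlation,
   Fisher r-to-z; binarize by keeping the strongest edges at each sparsity
   *s* ∈ {0.07, 0.08, …, 0.30} (edge count = round(s·N(N−1)/2)).
5. **Graph metrics** — ten global properties (Cp, Lp, Eglobal, Elocal,
   assortativity α, synchronizability S, hierarchy β, and the normalized
   γ = Cp/Cp_null, λ = Lp/Lp_null, σ = γ/λ against degree-preserving
   Maslov–Sneppen rewired nulls) and six nodal properties (degree,
   betweenness, clustering, efficiency, path length, local efficiency),
   each swept over the sparsity grid and summarized by trapezoidal AUC.
6. **Inference** — pooled two-sample t-tests on AUC (and per sparsity),
   Bonferroni correction (10 global comparisons; per nodal metric, the
   node count), and Pearson/Spearman correlation of network properties
   with clinical covariates (pack-years = years × cigarettes/day ÷ 20,
   FTND, age of first smoking) within the smoker group.

The synthetic generators produce (a) miniature tissue maps, 4-D BOLD runs
and realignment tables with controllable motion spikes, and (b) cohort
node series from a block factor model, x_i = √w·f_m(i) + √(1−w)·ε_i, whose
expected within-module correlation equals *w*, with a group effect on *w*
and a Gaussian-copula link between network coherence and age of first
smoking at a chosen correlation.

## Worked example

```python
import numpy as np
from wmconn import (SyntheticCohortSpec, NullSpec, make_cohort_connectomes,
                    correlation_matrix, default_sparsity_grid, metric_curves)

spec = SyntheticCohortSpec(n_per_group=2, n_nodes=64, n_modules=4, seed=3)
cohort = make_cohort_connectomes(spec)
conn = correlation_matrix(cohort.series[0])
curves = metric_curves(conn, default_sparsity_grid(), NullSpec(n_nulls=10, seed=0))
for name in ("cp", "gamma", "lambda", "sigma"):
    c = curves.global_curves[name]
    print(name, round(c.values[8], 3), round(c.auc, 4))
```

prints

```
cp 0.716 0.1752
gamma 4.623 0.9693
lambda 2.779 0.5274
sigma 1.663 0.4668
```

i.e. at sparsity 0.15 this modular connectome is 4.6× more clustered than
its degree-matched nulls (γ) at 2.8× the characteristic path length (λ),
giving small-worldness σ = 1.66 > 1; the AUC column is each curve's
trapezoidal integral over the 0.07–0.30 grid, the threshold-free
per-subject summary that the group statistics operate on.

The `examples/` scripts walk one capability each (synthetic subject,
masking + parcellation, connectome + metrics, group inference, full
pipeline), and the `wmconn` CLI exposes the stages as subcommands
(`simulate`, `mask`, `parcellate`, `clean`, `connectome`, `metrics`,
`stats`, `run-all`).

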