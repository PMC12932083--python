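# Methods

## Pipeline model

`wmconn` analyses resting-state BOLD signal restricted to white matter.
All image inputs are assumed co-registered on a shared voxel grid
(tissue-probability maps in [0,1], a 4-D BOLD run, a T×6 realignment
table per subject); spatial normalization and segmentation themselves
are upstream of this package. The processing chain and its defaults:

| stage | parameter | default | meaning |
|---|---|---|---|
| individual mask | threshold | 0.90 | WM probability must *strictly exceed* the cut (the stricter reading of a hard 90% rule) |
| group mask | overlap | 0.80 | voxel kept iff present in ≥ ceil(0.8·n) subjects (at-least reading) |
| volume drop | n_drop | 10 | discard initial frames (T1 saturation) |
| scrubbing | FD threshold | 0.5 mm | Power-convention FD: Σ\|Δtrans\| + 50 mm · Σ\|Δrot\|, fd[0] = 0 |
| scrubbing | window | 1 forward, 2 back | "forward" = later in time; the window is configurable because the mirrored convention (1 back / 2 forward) is also in circulation |
| bandpass | band | 0.01–0.10 Hz | linear detrend then ideal (frequency-domain) filter; Butterworth optional |
| parcellation | N, connectivity | 128, 26 | 26-adjacency because thin WM sheets fragment under 6-adjacency |
| sparsity grid | lo, hi, step | 0.07, 0.30, 0.01 | edges kept = round(s·N(N−1)/2), ranked by signed Fisher z |
| nulls | count, swaps/edge | 100, 10 | Maslov–Sneppen double-edge swaps; *attempted* swaps fixed at swaps/edge × edges |
| inference | α, family | 0.05, 10 or N | Bonferroni over the 10 global metrics; per nodal metric over the N nodes |

Order of operations: drop initial → FD/censor mask from motion →
detrend + bandpass on the *full* series → censored frames deleted
before correlation. Filtering precedes deletion so gaps do not leak
spectrally; censoring is deletion, never interpolation. No spatial
smoothing is applied anywhere (it manufactures local spatial
correlation between neighbouring WM voxels).

## Parcellation

Region growing with the smallest-volume-first discipline: N distinct
seed voxels drawn uniformly without replacement; each step, among
parcels that still touch unlabeled mask voxels, the one with the
smallest current size (ties to the lowest id) claims one voxel chosen
uniformly from its unlabeled frontier. Voxels unreachable from any
seed (disconnected mask islands) are attached to the nearest parcel by
world-space Euclidean distance, so the output is always a complete
partition. Everything is a pure function of (mask, N, connectivity,
seed). On the bundled blob fixture the final max/min size ratio stays
below 1.5 across 50 seeds. Atlas naming of a random parcel uses the
modal atlas label over the parcel's voxels — a pragmatic rule, since no
principled one-parcel-one-tract mapping exists for random parcels.

## Graph metrics

All metrics operate on undirected binary graphs. Conventions, chosen
for finiteness at the sparse end of the grid where graphs disconnect:

* distances are BFS hop counts; unreachable pairs contribute 0 inverse
  distance (efficiency) rather than ∞ distance;
* Lp = 1/Eglobal and nodal nlp = 1/ne (harmonic convention). The
  mean-over-connected-pairs alternative is available via
  `path_convention="connected-mean"`. Isolated nodes report nlp = 0 —
  they carry no path information and the zero keeps cohort tables
  finite and rectangular;
* Cp is the mean node clustering 2tᵢ/(kᵢ(kᵢ−1)) with nodes of degree
  < 2 contributing 0;
* Elocal (and nodal nle) is the global efficiency of each node's
  neighbour-induced subgraph, 0 for degree < 2;
* assortativity is the Newman degree–degree Pearson correlation over
  edge endpoints; degenerate (regular) graphs return 0;
* synchronizability is λ₂/λ_max of the combinatorial Laplacian, 0 for
  disconnected graphs (λ₂ = 0);
* hierarchy β is minus the OLS slope of log ncpᵢ on log kᵢ over nodes
  with kᵢ ≥ 2 and ncpᵢ > 0; fewer than 3 usable nodes or zero degree
  spread returns 0 with a warning;
* betweenness is Brandes' algorithm (via networkx), unnormalized,
  fraction-of-shortest-paths definition.

γ, λ, σ divide Cp and Lp by their means over degree-preserving rewired
nulls. A rewire attempt draws two edges and an orientation and swaps
endpoints unless a self-loop or duplicate edge would result; the
attempt count (not the success count) is fixed so randomization effort
is comparable across graphs. Connectedness is not enforced in nulls.
The swap loop is numba-compiled; the double-edge swap preserves the
degree sequence exactly, which the test suite verifies across 100
seeds. AUC uses the composite trapezoid rule on the sparsity grid; a
single-point grid integrates to 0 with a warning. Edge ranking breaks
ties toward the lexicographically lowest node pair, which makes edge
sets nest along the grid and makes every sweep reproducible.

The admissibility rule for a sparsity grid (mean degree > 2·log N;
σ > 1 for every subject) is implemented with configurable log base:
log₁₀ is the default because the conventional grid floor of 0.07 at
N = 128 (mean degree 8.89) satisfies the log₁₀ bound (4.21) but not the
natural-log bound (9.70).

## Statistics

"Two-sample t-test under a general linear model" is implemented as the
pooled-variance Student's t (a one-factor GLM is exactly that), df =
n₁+n₂−2, with Welch behind a flag. Group contrasts are oriented
smoker-minus-control. Bonferroni families: the 10 global metrics; for
nodal metrics, the N nodes within each metric (the observed nodal
p-values ≈ 3×10⁻⁴ clear 0.05/128 but not 0.05/768, which identifies
the per-metric family as the operative one). Clinical correlations are
computed in smokers only — controls have no smoking covariates — via
Pearson or Spearman (tie-corrected ranks). No covariate adjustment is
applied; the design assumes matched groups.

## Synthetic data

**Volume generator.** A logistic radial fall-off produces a central
blob with WM probability up to 0.98, a GM shell and CSF rim summing to
≤ 1 voxelwise; default grid 16³ at 3 mm, 120 frames, TR 2 s (desk-scale
but timing-faithful). Ground-truth parcels are a seeded Voronoi
partition of the blob; every voxel of a parcel shares that parcel's
band-limited (0.01–0.10 Hz) latent signal plus independent noise, so
node-series extraction is testable against known ground truth. Motion
files carry smooth sub-0.2 mm background drift plus step displacements
at requested frames, so the FD trace spikes exactly there.

**Cohort generator.** Node series follow a block factor model: node i
in module m gets x_i = √w·f_m + √(1−w)·σ_noise·ε_i with independent
standard-normal factors per module and frame. At the default unit
noise scale the expected within-module correlation is exactly *w*
(0.4 by default, 4 modules, 128 nodes, 120 frames) and between-module
correlation is 0. Smokers receive w + effect, which raises clustering
and local efficiency monotonically; w + effect ≥ 1 is rejected as an
infeasible loading. Clinical covariates are drawn from the cohort
summary statistics (duration 4.40 ± 2.96 y, 16.23 ± 5.60 cigarettes/
day, onset 14.23 ± 2.57 y, FTND 7 ± 2), pack-years computed as
duration × cpd / 20; age of first smoking is coupled to each smoker's
realized modular coherence (mean within-module Fisher z) through a
Gaussian copula with target correlation r (default 0.35): the
coherence values are rank-transformed to normal scores and the onset
latent is r·z + √(1−r²)·noise.

**What the generator does not emulate.** Real WM connectomes carry
shared global BOLD variance, distance-dependent correlations and
hierarchically overlapping communities; the block model's modules are
statistically independent. One visible consequence: at sparsities
below ≈ 0.24 the binarized synthetic graphs contain no cross-module
edges, so they are disconnected 4-component graphs whose harmonic Lp
is large relative to well-mixed degree-preserving nulls, and the
small-world σ of the *weakest* realized module can dip below 1 around
s ≈ 0.08–0.12. Passing metric and inference tests on this generator
therefore demonstrates correctness of the machinery and calibration of
the statistics, not that the synthetic cohort reproduces the σ floor
(> 1.1) that real, globally connected WM networks show across the same
grid. No hemodynamic response, physiological noise or scanner
artefacts are simulated.

## Simulation sizes used by the test suite

The calibration suite runs the full generator → connectome → Cp-AUC →
t-test chain at 32 nodes: 200 null replicates at 12+12 subjects for
type-I error (checked against the exact binomial 95% band around
α = 0.05), 30 replicates at 42+42 with effect = 0.35 — which realizes
a pooled-SD effect of d ≈ 1.0 on Cp AUC at this node count — for
power, and 40 replicates for copula-correlation recovery (mean
estimate within ±0.06 of the 0.35 target). These sizes are the
package's chosen desk-scale study conditions; the per-replicate
machinery is identical at any cohort size.

## Known limitations

* Weighted-graph metric variants, partial/wavelet/dynamic
  connectivity, modularity, rich-club and NBS inference are out of
  scope.
* The scrubbing sentence it implements ("removed the signal value …
  one forward neighbour and two back neighbours") is deletion;
  regression-based scrubbing is not offered.
* Nodal nlp = 0 for isolated nodes is a reporting convention, not a
  topological statement; interpret nodal path-length contrasts at very
  low sparsity with care.
* The null-rewiring seed stream is derived per (sparsity, subject) via
  `numpy.random.SeedSequence`, so results are reproducible but not
  comparable across different grid resolutions.
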