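# Methods

This note documents the models, conventions, and design decisions behind
`connsweep`, in the spirit of the methods documentation of simulation and
statistics packages. It states no empirical claims beyond what the test
suite and `scripts/acceptance.py` compute.

## Pipeline overview

The unit of analysis is a cohort of subjects, each represented by a T × N
matrix of ROI time courses (T volumes, N regions). The pipeline is:
preprocess → Pearson/Fisher-z connectivity → binary graphs over a sparsity
sweep → global and nodal graph metrics → normalization against
degree-matched random networks → trapezoidal AUC over the sweep →
permutation group inference and training-duration correlations.

## Signal preprocessing

Order is fixed: discard initial volumes (default 4 of 120), per-ROI linear
detrend (OLS line, which also removes the mean), ideal band-pass, nuisance
regression.

* **Band-pass (0.01–0.08 Hz).** Implemented as an ideal frequency-domain
  filter: every DFT coefficient whose frequency lies outside the closed
  band is zeroed (operating on the real FFT preserves conjugate symmetry).
  This is the convention of the common resting-state toolkits; a Butterworth
  filter would be a reasonable alternative but is not provided. The ideal
  filter is exactly idempotent, which the tests exploit.
* **Nuisance regression.** The design contains an intercept, any supplied
  confound regressors, and (by default) the global signal, defined at ROI
  level as the mean across ROI columns of the filtered data. Residuals are
  exactly orthogonal to the design. The synthetic generator stores the true
  confounds it injected, so the pipeline can regress exactly the right
  signals — an idealization relative to real preprocessing, where confound
  estimates are noisy.

One consequence worth knowing: with 116 retained volumes at TR = 2.34 s,
the 0.01–0.08 Hz band holds ~19 Fourier bins, i.e. ≈ 38 effective degrees
of freedom. Sample correlations therefore carry a noise SD of ≈ 0.16
regardless of the true effect — the dominant noise source everywhere
downstream.

## Connectivity

Pairwise Pearson correlation between ROI columns, diagonal fixed at 0,
Fisher z = artanh(r) applied off-diagonal. The z matrix is derived lazily so
that a degenerate r = ±1 (duplicate columns) is representable; requesting z
then raises. Zero-variance columns raise with the offending ROI named.

## Network construction

At sparsity S, the K = round_half_up(S · N(N−1)/2) node pairs with the
largest **signed** z are connected. Conventions:

* **Signed, not absolute.** Thresholding ranks correlation strength;
  strongly negative edges are never selected. Rank by |z| instead by
  passing a pre-transformed matrix if desired.
* **Rounding.** Round-half-up, observable at N = 110, S = 0.10:
  0.10 · 5995 = 599.5 → 600 edges.
* **Ties** are broken lexicographically by (i, j) and logged, so a
  degenerate all-equal matrix still yields a deterministic graph.

## Graph metrics

All printed conventions of the classic small-world literature, on
undirected unweighted graphs:

* C_P = mean over nodes of E_i / (d_i(d_i−1)/2), where E_i is the edge
  count of the subgraph induced by i's neighbors; the term is defined as 0
  for degree < 2 (the ratio is otherwise undefined).
* E_glob = mean over ordered pairs of 1/L_ij with 1/∞ = 0.
* **L_P = 1/E_glob (harmonic form).** The printed equation makes L_P the
  reciprocal of the mean inverse distance, which stays finite on
  disconnected graphs. The arithmetic mean over reachable pairs — the other
  convention in circulation — is available via
  `global_metrics(..., path_length="arithmetic")`; the package does not
  guess which one a given legacy toolkit used. The identity
  L_P · E_glob = 1 is exact under the default and is asserted in tests.
* E_loc = mean over nodes of E_glob of the neighbor subgraph (0 for
  neighborhoods smaller than 2).
* D_nod, E_nod as usual; B_nod is Freeman's unnormalized betweenness,
  counting each unordered pair once, computed by Brandes' dependency
  accumulation. Its output is validated against exhaustive path enumeration
  on hundreds of small random graphs.

Distances, path counts, betweenness, and local efficiency run in JIT-compiled
(numba) kernels over a CSR adjacency; a full sweep touches tens of thousands
of graphs, so the inner loops are the only performance-critical code.

## Null models and small-worldness

γ = C_P/C_P^rand, λ = L_P/L_P^rand, σ = γ/λ, with the rand values being
arithmetic means over degree-matched random networks produced by
Maslov–Sneppen double-edge swaps (pick edges (a,b), (c,d) on four distinct
nodes, replace with (a,d), (c,b) unless either exists). Choices:

* **Swap depth**: ceil(10 · |E|) attempted swaps per null by default —
  standard practice; configurable. With zero swaps the nulls equal the
  input and σ = 1 exactly (identical null values are averaged exactly).
* **Nulls are not forced to be connected**; the harmonic L_P handles
  disconnection gracefully. A null with C_P = 0 or infinite L_P is excluded
  from the means with a logged count; all-degenerate nulls raise.
* **Null count**: 100 by default, 20 in the heavy end-to-end checks (the
  mean over 20 nulls has relative SE well under 1% at these densities).
* RNG streams derive from (seed, subject, threshold index), so any single
  normalization is reproducible in isolation and results do not depend on
  execution order or thread count.

## AUC and inference

* **Trapezoidal AUC** over the sparsity grid — exact for the piecewise
  linear curves the sweep produces. A non-finite curve value (possible for
  L_P on a disconnected graph) makes the AUC undefined; the record is
  flagged rather than silently dropped.
* **Permutation tests** use the difference of group means as statistic.
  The null re-splits the pooled subjects into the original group sizes;
  Monte-Carlo mode uses the add-one estimator
  p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1), and the test switches to
  exhaustive enumeration automatically when the number of distinct splits
  is at most n_perm (there p = count/total; the observed split is itself
  enumerated so p > 0). All-equal pooled values give p = 1.
* **Region flagging** applies the at-least-one-nodal-metric rule: a region
  is flagged when min(p_degree, p_efficiency, p_betweenness) < α. This
  union inflates the per-region type-I error above the per-metric α (three
  correlated tests), which is why the per-metric p-values and directions
  are always written out; users wanting strict control should apply their
  own correction to those.
* **Training correlations**: Pearson r of each region's nodal AUC against
  training years within the trained group, two-sided p, Bonferroni
  significance at α/110 (the parcellation size), with the uncorrected 0.05
  outcomes also reported.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets, not real
BOLD physics:

* **Covariance**: Σ = w·A + b·I with A a Watts–Strogatz graph
  (ring lattice, k nearest neighbors, random rewiring) — defaults N = 110,
  k = 10, rewire 0.1, w = 0.25, b = 1.5, giving adjacent-ROI correlations
  of 1/6 and a small-world covariance topology. Positive-definiteness is
  checked at build time and violations raise with the offending eigenvalue.
* **Group effect**: for group A only, entries on existing edges among the
  effect ROIs (default the five consecutive regions 106–110, so all ten
  pairs are lattice edges) are incremented by `effect_delta`
  (default 0.35). The default is the largest increment that kept the
  covariance positive-definite across a 400-seed scan of base graphs
  (minimum eigenvalue margin 0.026 at 0.35; failures appear by 0.40).
* **Temporal structure**: i.i.d. multivariate normal rows, then AR(1)
  smoothing x_t ← φx_{t−1} + √(1−φ²)x_t with φ = 0.3 (a typical lag-1 BOLD
  autocorrelation at TR ≈ 2.3 s), which preserves the stationary
  covariance.
* **Confounds**: a global random-walk signal added to every ROI
  (amplitude 1.0), a linear drift (1.0), and six motion-like random-walk
  regressors entering each ROI with standard-normal loadings (amplitude
  0.3); all regressors are standardized to unit variance before scaling
  and stored with the subject for exact removal.
* **Training durations**: Normal(12.47, 1.50²) years, truncated at zero by
  redraw (at these parameters truncation is a ~8σ event).
* Per-subject seeds derive deterministically from the cohort seed; an
  identical spec yields a bit-identical cohort.

What passing tests on this generator do **not** show about real data:
no physiological (cardiac/respiratory) noise, no motion beyond
regressor-shaped confounds, no spatial hemodynamic structure, no
inter-subject topology variability beyond sampling noise, and confounds
that are removable exactly rather than estimated.

### Sensitivity of the planted effect

The planted covariance increment produces a large per-edge effect (group
difference in edge correlation ≈ delta/b ≈ 0.23 at the default), but
rank-based binarization converts it into a nodal degree contrast of only
one to two edges: the effect ROIs have at most ten mutual edges, their
selection saturates at high sparsity, and global-signal regression
redistributes part of the planted gain across the matrix. Against a
between-subject nodal-AUC SD driven by the ≈ 38 effective degrees of
freedom of the band-passed signal, per-region power at α = 0.05 stays
modest at any positive-definite delta. The package's power check
(100 synthetic cohorts) measures and reports this honestly rather than
overstating recovery: with defaults, a typical cohort flags some but not
most of the planted regions. Detecting such localized covariance effects
reliably at n ≈ 16/17 requires either longer runs (more effective dof) or
effects spanning more region pairs.

## Problem sizes used in validation

Oracle-equivalence checks run on hundreds of random graphs with N ≤ 12,
where exhaustive enumeration is exact and fast. End-to-end checks run the
default 33-subject, 110-ROI cohort with 20 nulls per graph; the
permutation calibration uses 1000 simulated datasets × 1000 permutations;
the planted-effect power check uses 100 cohorts at 1000 permutations.
These sizes keep the full validation suite comfortably within a desk-scale
compute budget while leaving Monte-Carlo error well below the tolerances
asserted.

## Known limitations

* ROI level only: no voxel-wise maps, no NIfTI handling (a documented
  extension point), no cluster-level corrections.
* Binary undirected graphs only; no weighted-graph metrics.
* The union flagging rule is reported as specified despite its inflated
  per-region type-I error (see above).
* The harmonic-vs-arithmetic path-length ambiguity is exposed as an option
  rather than resolved.
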