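# Methods

`connlife` implements a structural-connectivity lifespan analysis as a
tested, reusable pipeline: quality control and consistency thresholding
of subject-level connectomes, weighted graph-efficiency metrics,
behavioral partial least squares (PLS) with permutation, bootstrap and
split-half inference, rolling age-window brain–behavior correlations
with BCa intervals, and whole-brain regression models of local
efficiency. Because raw lifespan dMRI cohorts are not desk-scale, the
package ships a synthetic-cohort generator with *planted* latent
structure so that every stage can be validated by recovery against a
known ground truth.

## Synthetic cohorts

The generator emulates the qualitative features such analyses assume:

* **Behavior.** Ages are uniform on a configurable range (default
  18.5–88.92 years); sex is balanced Bernoulli(0.5); fluid intelligence
  is a Cattell-like score `a·z(age) + s·z(e)` with the noise `e`
  exactly orthogonalized against age, so the realized age–FI Pearson
  correlation equals the configured target (default −0.65) exactly for
  any cohort size. Setting the FI noise SD to zero degenerates to a
  noiseless linear map with correlation ±1.
* **Geometry.** Regions receive random 3D coordinates in two
  lateralized blocks (x < 0 left, x > 0 right), giving a testable
  intra/inter-hemispheric classification. Distances are Euclidean (mm).
* **Group template.** Edge weights decay exponentially with distance
  (e-folding length 30 mm, in the range reported for connection
  probability fall-off in mammalian cortex), sparsified to a target
  density by keeping the heaviest edges. A minimum spanning tree over
  distance is always retained so the template is connected; pure
  top-weight selection keeps only short intra-hemispheric edges and can
  disconnect small parcellations.
* **Subjects.** Per-subject log-weights add lognormal noise
  (default SD 0.5) and the planted multiplicative effects; effects act
  on the log scale because streamline probabilities must stay
  nonnegative. Each subject additionally misses each template edge with
  a small dropout probability (default 0 for strict reproducibility of
  the degenerate-noise identity; 0.05 in the default study conditions),
  mimicking tractography's failure to find some true connections —
  without it every subject shares one zero pattern, density QC is
  vacuous, and mean SC distance is constant (a collinear regressor).
  One global rescale puts all weights in (0, 1].
* **Planted effects.** A component is a set of edges (or regions,
  expanded to incident/neighborhood edges) whose log-weights shift by
  `loading_age·z(age) + loading_fi·z(residual cognition)` per subject.
  The default study spec plants one intra-hemispheric edge component of
  120 template edges with loadings (−1.0, +0.6): strong enough that a
  rank-1 latent variable dominates the ~2000-edge noise floor (the
  attainable salience cosine is governed by support size × per-edge
  correlation against p/n), weak enough that per-edge correlations stay
  well below 1.

What the generator does **not** emulate: spatial autocorrelation of
noise across neighboring edges, heteroscedastic age-dependent noise,
non-lognormal weight distributions (the lognormal choice is an
assumption; empirical streamline-probability distributions are not
published), scanner/site effects, and head-motion artifacts. Passing
recovery tests therefore demonstrates correctness of the *estimators*,
not robustness to every real-data pathology.

## Quality control

Order of operations (deliberately non-iterative, matching the usual
reporting order): (1) group consistency mask — an edge is kept iff
present (weight > 0) in at least 50% of subjects, boundary inclusive;
(2) subjects without behavioral scores are excluded; (3) subjects left
with any fully disconnected region are excluded; (4) a single density
pass excludes subjects whose post-mask density lies 3 SD or more from
the mean. Density is the fraction of possible undirected pairs with a
nonzero connection and is computed after masking (recorded in the QC
report header). Two numerical decisions matter:

* the SD is the **population** SD. With the sample SD, one outlier
  among n subjects can deviate at most (n−1)/√n SDs (Samuelson's
  inequality) — 2.85 at n = 10 — so a 3-SD rule could never fire in
  small cohorts; the population-SD bound is √(n−1), which an extreme
  outlier among 10 attains exactly;
* the boundary is inclusive ("3 SD or more") with a 1e-12 absolute
  slack so the exact-boundary case is not lost to rounding.

A zero SD (all densities equal) excludes no one: an outlier is
undefined.

## Graph metrics

Edge lengths are inverse weights, `l_ij = 1/w_ij` (the standard choice
for connectivity weights; it keeps every efficiency in [0, 1] when
weights are ≤ 1, and is recorded in the metric table's metadata for
auditability). Shortest paths are Dijkstra per source.

* **Nodal efficiency**: mean inverse shortest-path length from a region
  to all others, `E_nodal(j) = (N−1)^{-1} Σ_{i≠j} 1/l_ij`; disconnected
  pairs contribute 0.
* **Local efficiency**: the same mean computed inside the subgraph
  induced by a region's neighbors after removing the region itself,
  normalized by `N_G (N_G − 1)`; regions with fewer than two neighbors
  score 0. Path lengths are restricted to the subgraph and use the
  original weights (no re-weighting by the stem edges — the simpler
  variant).
* **Clustering**: Onnela's weighted coefficient on weights rescaled by
  the maximum weight.
* **Characteristic path length**: mean of finite off-diagonal
  shortest-path lengths.
* **Small-worldness**: σ = (C/C_null)/(L/L_null) against
  degree-preserving Maslov–Sneppen rewired nulls (default 10 nulls,
  10·E attempted swaps each) with the original weight multiset shuffled
  onto the rewired topology. Rewiring that disconnects the graph is
  retried; after retries the largest component is used with a warning.
  A swap factor of 0 keeps the original graph (and weights) as its own
  null, making σ exactly 1 — a useful degenerate check.
* **Whole-brain summaries**: SC total (sum of streamline probabilities
  over undirected pairs) and mean SC distance (mean distance over pairs
  with a retained connection).

## Behavioral PLS

The cross-block matrix is the behaviors × brain-variables Pearson
correlation matrix R (standard behavioral PLS); its SVD
`R = U diag(S) Vᵀ` yields latent variables. Signs are fixed by
orienting each LV so its largest-magnitude behavior salience is
positive (arbitrary but documented; reported LV–behavior correlation
signs depend on it). Zero-variance brain columns are dropped with a
warning; constancy is detected by `ptp == 0`, since a float-constant
column has a standard deviation of ~1e-16, not 0.

* **Permutation test**: rows of Y are permuted jointly (preserving the
  behavior covariance) and the singular values recomputed;
  `p_k = (1 + #{S*_k ≥ S_k})/(n_perm + 1)` — the add-one estimator
  avoids zero p-values and matches the conventional "p < 0.001" floor
  at 1000 permutations.
* **Bootstrap ratios**: subjects are resampled with replacement; each
  resampled SVD is aligned to the original by the orthogonal Procrustes
  rotation of the behavior saliences, applied to the singular-value-
  scaled brain saliences `V diag(S)`. BSR = original scaled salience /
  bootstrap SE. Bootstrapping the unit-norm V instead is measurably
  anti-conservative (the bootstrap top singular value is biased upward,
  shrinking null-edge saliences and understating their SE: false-
  positive rates near 17% under a pure null, vs ≈ 4.7% for the scaled
  form). Resamples with a constant column are redrawn (bounded; a fully
  degenerate cohort errors out). Percentile 95% CIs are reported for
  the correlations between bootstrap brain scores and each behavior.
* **Split-half reproducibility**: subjects are halved at random (the
  larger half takes the odd subject), PLS is fit in each half, and two
  similarities are computed per LV: a singular-value similarity that
  cross-projects each half's saliences onto the other half's
  correlation matrix, `(U1ᵀR2V1 + U2ᵀR1V2)/(2·S_full)`, and a
  singular-vector similarity, the absolute correlation of matched brain
  saliences (greedy matching over LVs). `Z = mean/SD` over splits. Null
  Zs repeat the whole procedure on Y-permuted data (10 permutations,
  averaged), and an LV is flagged reproducible iff `Z_svec > 2 +
  Z_svec_null`. The cross-projection form was chosen over the raw
  product of half singular values because the latter has a strongly
  positive mean under permutation (its null Z is ~10, making the
  threshold useless), whereas cross-projection is zero-mean under the
  null — the behavior the reproducibility thresholding presumes.
* **Reliable patterns**: variables with |BSR| at or above a threshold
  (default 2, the z-like convention) are split by sign; edge-mode
  reports add per-region degree over selected edges, hub regions
  (degree > 3), and intra-left/intra-right/inter-hemispheric
  percentages (summing to 100).

Group (sex) PLS stacking is not implemented: sex enters only the
regression models.

## Lifespan statistics

* **Rolling correlation**: windows of fixed width (default 10 years)
  start at integer years from ⌊min age⌋ to ⌊max age⌋ − width + 1
  inclusive, stepping 1 year; membership is half-open
  [start, start + width). This convention yields 62 windows for ages
  spanning 18.5–88.9. Windows with fewer than 3 subjects report a null
  correlation. Each window's Pearson r gets a 95% BCa interval.
* **BCa bootstrap**: bias correction z₀ from the fraction of bootstrap
  replicates below the point estimate (ties counted half, proportions
  clamped away from 0/1), acceleration a from jackknife skewness;
  degenerate bootstrap distributions collapse the interval to the point
  estimate. Rows are resampled jointly so paired statistics work.
* **t tests**: paired tests are one-sample tests on differences
  (df = n − 1; a zero-variance zero-mean difference returns t = 0,
  p = 1); independent tests use the Welch correction by default with a
  pooled-variance option (df = n₁ + n₂ − 2) for the classical
  convention.
* **Regression models**: ordinary least squares with intercept on mean
  local efficiency over a configured region set. Model 1 uses age, sex
  (reference female), small-worldness and SC total; Model 2 swaps SC
  total for mean SC distance; Model 3 includes both. CIs are t-based
  95% intervals. A design with condition number above 1e10 (after
  column scaling) errors, naming near-collinear term pairs. Group
  differences are judged by the CI-overlap rule — "different" iff the
  two 95% CIs are disjoint — which is conservative relative to an
  interaction test but is the reporting convention mirrored here; no
  further multiple-testing correction is applied.

## Pipeline

`run_pipeline` executes qc → metrics → pls → rolling → regress in
dependency order (a skipped prerequisite raises an error naming the
stage). Every stochastic stage draws its seed from the run seed through
a `SeedSequence` spawn tree; the config and its hash are embedded in
`report.json`, and wall-clock timings are stripped from the serialized
report, so a rerun with the same config is byte-identical. The rolling
stage follows the study design: nodal-efficiency curves use the regions
positively related to cognition in older adults, local-efficiency
curves the regions positive in younger adults; the regression stage
uses the regions negatively related in older adults (falling back to
all regions when a pattern is empty). The reduced profile caps
resampling at 100 iterations for quick runs; the full profile uses
1000.

## Problem sizes

The test suite and `scripts/acceptance.py` run the recovery study at
300 subjects × 64 regions (≈ 500 retained edges), inference at 200
permutations / 1000 bootstraps / 100 splits, calibration studies at
500 replicate datasets and 1000 BCa simulations with 500 bootstrap
replicates, and metric/regression stages at 120 subjects with 5
small-world nulls. These sizes give Monte-Carlo error comfortably
inside the tested tolerance bands while keeping a full run around a
minute on one core; all counts are configurable up to the full
1000-iteration profile.

## Known limitations

* The split-half similarity formulas are this package's concrete
  definitions of a method whose exact published form varies; only their
  calibration behavior (signal ≫ threshold, null below threshold) is
  guaranteed, not numeric equality with any particular toolbox.
* BSR selection at |BSR| ≥ 2 has a null false-positive rate near the
  nominal 4.6% but fluctuates with the data realization; it is a
  per-variable screen, not an FDR-controlled procedure.
* Whether empirical pipelines compute density before or after
  consistency masking is often unstated; here it is after, and recorded
  in the QC report.
* The inverse-weight length transform is one of several defensible
  choices (inverse-log is another); it is recorded in output metadata.
* Cross-sectional only: no longitudinal or mixed-effects modeling.
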