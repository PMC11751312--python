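# Methods

This note documents the models, the synthetic-data generative process, the
numerical choices and the design decisions taken where the procedure was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A cohort is a phenotype table plus index-aligned stacks of per-subject
matrices on one shared parcellation.  Internally all node indices are
0-based; file-facing `node_id` is 1-based.  FC matrices are handled as raw
Pearson r by default (`fc_mode="r"`, entries validated to [−1, 1]); a
Fisher-z mode is available and all edge-level machinery is agnostic to the
choice.  Connectomes are flattened to the row-major upper triangle
(i < j), giving n(n−1)/2 edges — 27,730 for the default 236-node
parcellation.  The per-network proportions of the default parcellation
(DMN 90, FPN 60, DAN 42, VAN 44) follow the four association networks of a
400-parcel, 7-network cortical atlas; the real node table is user-supplied
in practice (`parcellation.tsv`), because the retained-subset composition
is study-specific.

Matrices serialise as one dense TSV per subject with a JSON manifest
(subject order, parcellation hash), or as a single `.npz` stack; both
readers are supported.  Validation is strict at load time: subject-id
alignment across files, symmetry within 1e−10, no missing phenotype cells
(errors name the subject and column).

## Synthetic cohorts

The generator (`narraging.simulate`) emulates the statistical structure the
analyses assume, at the connectivity-matrix level (no BOLD time series,
motion or scanner effects):

* **Ages**: truncated normal, mean 68.26 y, sd 8.20 y, range [50, 90] —
  the demographic profile of the motivating cohort design (n = 740).
* **Cognitive domains** (episodic memory, executive function, attention,
  verbal fluency, spatial construction, general screen): unit-variance
  scores with fixed age loadings (memory declining most, fluency
  age-stable).
* **Macro score**: piecewise-linear age decline (−0.015/y, an extra
  −0.08/y past the change point at 72) plus cognitive-domain contributions
  plus noise.  With the default noise scale this yields corr(age, macro)
  around −0.6 and a recoverable break at 72.  The slopes were chosen so the
  age trend is clear without making the score an age proxy.
* **Micro score**: chiefly verbal fluency plus noise; corr(age, micro)
  is near zero by construction.
* **FC**: each subject's matrix comes from a rank-5 latent factor model
  with per-subject loading jitter (guaranteeing valid correlation
  structure), mapped to Fisher-z, plus a small iid z floor (sd 0.02).
  Planted effects are additive in z-space on chosen edges, scaled by the
  edge's baseline across-subject spread times r/√(1−r²) so that the
  population edge–score correlation approximates `effect_r` (default 0.3;
  verified by a Monte-Carlo test).  Matrices are mapped back through tanh
  and projected to the nearest valid correlation matrix by spectral
  clipping (eigenvalue floor 1e−6, diagonal renormalised), so every FC
  matrix is symmetric, unit-diagonal and PSD.
* **Aging edges**: compensatory (declining) edges are hub-to-region edges
  whose macro coupling is scaled by max(0, c₀ ± slope·age_z) with
  c₀ = 1.5 and per-edge slopes ~ U(0.8, 1.2)·`trend_slope` (default 1.0),
  on their own coupling scale `aging_effect_r` = 0.5.  These values were
  fixed once by a power calculation: they make the window-wise trend
  detectable against the overlapping-window permutation null at desk-scale
  cohort sizes (n ≈ 500).  They are conditions of the simulated study, not
  estimates of any real effect size.  Compensatory edges additionally carry
  a spatial-construction coupling and declining edges an episodic-memory
  coupling, giving the decoding stage a planted answer.
* **GMV**: node volumes share a hub-cluster latent factor whose loading on
  compensatory (declining) target nodes increases (decreases) with age —
  the window-wise hub-target covariance then trends with age.
* **WM**: overdispersed counts (gamma-Poisson, shape 10) whose log-mean is
  linear in the edge's planted FC age-trend with slope `wm_coupling`
  (default 2.0).

Everything derives from one seed via stable per-component sub-streams;
identical seeds give bit-identical cohorts.  The planted ground truth
(edge sets, hub nodes, region nodes, coupling slopes, behavioural loadings)
is returned and serialisable, making every downstream stage testable as a
recovery problem.

**What passing tests do and do not show.**  The generator reproduces the
*dependence structure* the methods rely on (edge–score correlations,
age-varying couplings, covariance trends) but not the full realism of
imaging data: no spatial autocorrelation beyond the factor structure, no
site/motion confounds, Gaussian behavioural noise, and effect sizes chosen
for comfortable statistical power.  Recovery results demonstrate method
correctness and calibration, not expected field performance on real
cohorts.

## CPM

Defaults: screening permutations 1000, α = 0.01 (two-sided, shared shuffle
set so the null is re-enumerable from the seed), 10 CV folds within the
training set, stability ≥ 0.9 of folds (inclusive at the threshold), 10%
held-out test fraction, 1000 model permutations.  The held-out split
precedes any selection; fold screening sees only fold-training subjects.
Positive and negative edges are combined into one signed summary feature by
default (`edge_polarity` configurable).  An empty validated set returns an
explicit "no predictive edges" result, not an exception.  The
fold-stability rule is this package's concrete reading of edge
"validation" across resamples; the screening α and fold count are not
prescribed anywhere and are exposed in `CPMConfig`.

## Hub topology

Authority scores are computed by power iteration on the weighted adjacency
with two numerical safeguards: a positive diagonal shift (same
eigenvectors; removes the ±λ oscillation of near-bipartite hub-seeded
graphs) and per-connected-component iteration with components recombined in
proportion to spectral radius.  For a connected graph this equals
eigenvector centrality (checked against dense eigendecomposition at 1e−8);
for disconnected graphs it is a deterministic regularisation of the
degenerate HITS limit, whose mass would otherwise depend on tie-breaking
between components.  Rankings break ties by descending score then ascending
node id.

Community structure: Louvain run 100 times (resolution 1.0) with distinct
sub-seeds; the co-assignment frequency matrix is clustered by Ward linkage
on 1 − frequency and cut at 4 communities.  This consensus construction is
the one reading under which a hierarchical-linkage step applies to
partition outputs.  Both the run count and the community count are
configurable.

Dice overlap of node sets uses the exact 2|A∩B|/(|A|+|B|) with a null that
draws sets of the observed sizes without replacement from the parcellation.

## Enrichment and gradients

Edge-level enrichment follows the printed expectation
E_i = (total selected edges) × |network| / 236 by default.  Note the
denominator quirk: a node has only 235 possible partners, so part of each
expectation is allocated to the focal node's own slot; a strict
`denom = n−1` option exists.  The permutation null re-assigns each selected
edge's outer endpoint uniformly over the 235 candidates (endpoint
shuffling; a network-label shuffle would be the main alternative and is not
what the size-preserving description suggests).  Community enrichment uses
E_i = |C| × |network| / n with community-size-preserving label
randomisation.

Gradients: per-subject PCA of the FC matrix rows (m = 2 components by
default), aligned to the cohort-mean template by orthogonal Procrustes;
group contrasts are node-wise two-sample t-tests under BH-FDR.  Groups are
the top third by macro and by micro score with overlapping subjects
removed.  BH-FDR is the single multiple-testing procedure used throughout
the package.

## Sliding-window aging trends

Windows hold exactly 30 subjects over the age-sorted cohort.  The default
is step-1 sliding (a dense window series is what makes a trend correlation
meaningful); disjoint blocks (trailing remainder merged into the last
window) and equal-width age bins are implemented as robustness variants,
and significant-edge signs agree across variants on default synthetic
cohorts.  The per-edge trend statistic is the correlation of the
*Fisher-z-transformed* window coupling with window mean age — the
z-transform is variance-stabilising and expands the saturated high end of
strong couplings; a raw-r option is retained.

Significance: ages are shuffled across subjects and the entire window
pipeline re-run per permutation.  This is the only null that respects the
strong positive dependence of overlapping windows (naive analytic p-values
on 400+ overlapping windows would be wildly anticonservative — the
effective number of independent windows is roughly n/30).  Null trend
statistics are pooled across edges before computing p-values: the edges
share one window structure and a comparable scale, and per-edge nulls at
feasible permutation counts cannot resolve p below 1/(B+1), which BH
across thousands of edges cannot act on.  A per-edge null remains available
(`pooled_null=False`).  Edges with q < 0.05 are signed; nodes are labelled
compensatory/declining by majority vote of their significant incident edges
(the aggregation rule is this package's choice; no rule is prescribed).

## Cognitive decoding

Method 1 predicts each domain score from the FC values between hub and
region node sets on a held-out test sample (74 subjects at full scale),
with ridge regularisation engaged automatically once the feature count
reaches half the training size (CV-chosen penalty), and label-permutation
significance.  Method 3 fits a CPM per domain, ranks its contributing-edge
graph by authority, and Dice-compares the top-k with the region set.  The
combined verdict requires both methods significant at α = 0.05 — the
original design had a third, meta-analytic decoding route that depends on
an external database and is out of scope here, so concordance of two
methods replaces concordance of three.

## Structural validation

SCN: across-subject GMV correlation of each hub-target pair per age
window; trend and permutation scheme as in the aging analysis.  The
contrast **Ms** is defined here as the difference between the mean
significant trend among compensatory targets and among declining targets,
with significance from permuting the target labels; this
contrast-of-means construction is one consistent reading of an
under-specified statistic and is antisymmetric under label swap by
construction.  WM regression: per hub-target edge, standardised log1p mean
fiber count (log1p because counts are heavy-tailed) predicts the edge's FC
age trend via ridge with a CV-tuned penalty, evaluated on held-out edges.

## Behavioural statistics

SUR is Zellner feasible GLS: equation-wise OLS residuals give the
cross-equation covariance, then joint GLS; cross-equation Wald χ² (df = 1)
tests coefficient equality.  With a shared design SUR collapses to OLS
exactly (tested).  Comparing coefficients *between age subgroups* is not a
SUR problem (disjoint subjects have no estimable cross-equation
covariance); it is implemented as a group-interaction Wald test, the
large-sample equivalent.

Shapley R² is the exact Shapley–Owen enumeration over all 2^p subsets
(p ≤ 12; p = 5–6 here), so shares sum to the full-model R² to machine
precision and tests carry no Monte-Carlo noise.

Turning point: the change point is the breakpoint of the best continuous
two-segment (hinge) fit over a 0.25-y grid spanning the inner 10–90% age
range.  Because the breakpoint is chosen to maximise fit, the naive
fixed-breakpoint F reference is anticonservative; significance is instead
calibrated by a residual-permutation null of the sup-F statistic (200
draws).  A penalised B-spline smooth (df 6) describes the trend for
inspection, and the bootstrap percentile interval resamples subjects.
Monotone-linear data yield an explicit "no turning point" result.  The
estimator is equivariant to affine transforms of the response.

## Problem sizes

Default configurations target the full design (n = 740, 236 nodes,
27,730 edges, 1000 permutations).  The test suite and the acceptance
script run the same code on reduced parcellations (40–60 nodes with the
default network proportions), cohorts of 300 (null calibration) and 500
(recovery, seeds 1–10), and permutation counts of 100–500 — sizes chosen so
the whole validation battery runs in minutes on one CPU while keeping every
statistical property (calibration, power, identities) measurable.

## Known limitations

* The pooled permutation null assumes exchangeable trend statistics across
  edges; strong per-edge heteroscedasticity would argue for the per-edge
  option at higher permutation counts.
* Enrichment follows the printed 236 denominator by default even though a
  node has 235 partners (documented above).
* The WM regression is univariate per edge (fiber count → trend); a
  multivariate variant over edge sets is out of scope.
* Gradients use plain PCA; diffusion-map embeddings and kernel choices are
  not implemented.
* The generator plants effects additively in Fisher-z space; the spectral
  PSD projection can attenuate extreme planted couplings slightly (the
  effect-size Monte-Carlo test bounds this).
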