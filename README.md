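# narraging

Connectome-based prediction and aging-trajectory analysis of narrative
macro- and microstructure.

## The problem

Narrative ability in older adults has two separable levels: the
**macrostructure** (characters, events, the causal plot frame) and the
**microstructure** (basic linguistic measures such as lexical diversity and
sentence form).  The macro level declines with age — with an acceleration
after a change point in the early seventies — while the micro level is
largely age-stable.  This package implements the full statistical framework
for asking *which brain systems carry each level, and how that mapping
reorganises with age*, from multimodal imaging cohorts:

* a phenotype table (age, sex, macro/micro narrative scores, cognitive
  domain scores),
* per-subject resting-state functional connectivity (RSFC) matrices on a
  236-node parcellation restricted to four association networks
  (DMN, FPN, DAN, VAN; 27,730 edges),
* per-subject node-wise gray-matter volumes (GMV), and
* per-subject white-matter (WM) fiber-count matrices.

It is written for cognitive-neuroscience researchers doing
connectome-phenotype inference who want the whole pipeline — edge selection,
graph topology, enrichment, sliding-window aging trends, decoding and
structural validation — as tested, scriptable building blocks.

## The methods at its core

**Connectome-based predictive modelling (CPM) with permutation-constrained
selection.**  For a phenotype y and edge values x_e, every edge is screened
by its Pearson correlation r(x_e, y) with a permutation p-value (shared
shuffle set across edges); edges with p < α in at least a fraction of
cross-validation folds form the *validated* set.  A subject-level summary
feature Σ_e sign(r_e)·x_e enters a univariate regression, and generalisation
is r(ŷ, y) on held-out subjects with label-permutation significance.

**Hub topology and enrichment.**  Validated edges form an undirected
weighted graph; nodes are ranked by HITS authority (the principal
eigenvector for a symmetric adjacency), communities come from consensus
Louvain + Ward clustering, and per-network enrichment folds are
A_i / E_i with E_i the proportional-allocation expectation
(edges: E_i = total·|network|/236; communities: E_i = |C|·|network|/236),
tested by size-preserving permutation.

**Sliding age-window compensation analysis.**  Subjects sorted by age form
30-subject windows; per window each hub-seeded edge is correlated with the
narrative score, and the edge's *trend* is the correlation of its
(Fisher-z) window coupling with window mean age.  Significance uses an
age-shuffling permutation null with full re-computation (respecting the
overlap dependence), BH-FDR across edges; positive-trend edges are
*compensatory*, negative ones *declining*.

**Decoding and structural validation.**  Compensatory/declining region sets
are decoded by (1) predicting each cognitive domain from seed-to-region FC
and (2) Dice overlap with each domain's own CPM hub set.  Structurally, the
hub-target GMV covariance trend over age windows gives the contrast
Ms = mean significant trend (compensatory) − (declining), and a ridge
regression predicts each hub-target edge's FC aging trend from its WM
fiber count.

**Behavioural statistics.**  Multiple regression of narrative scores on
cognitive domains, Zellner SUR with cross-equation Wald χ² contrasts, exact
Shapley–Owen R² decomposition, and a change-point estimator (grid-searched
continuous hinge fit, sup-F significance calibrated by residual
permutation, penalised-spline smooth, bootstrap CI).

Because matched public cohorts do not exist, the package ships a
first-class synthetic-cohort generator (`narraging.simulate`) that emulates
the statistical structure of such a study — truncated-normal ages
(mean 68.26, sd 8.20, range 50–90), a macro score with a change point at 72,
a fluency-driven micro score, low-rank-factor FC with planted edge–score
correlations, age-varying compensatory/declining couplings, age-modulated
GMV covariance and WM–FC-trend coupling — and returns the planted ground
truth for recovery testing.

## Worked example

```python
from narraging import (SimulationConfig, simulate_cohort,
                       ConnectomePredictiveModel, CPMConfig)
from narraging.aging import AgingTrendAnalysis
from narraging.behavior import estimate_turning_point

cfg = SimulationConfig(n_subjects=500, n_nodes=60, seed=1,
                       n_signal_edges_macro=40, n_signal_edges_micro=40,
                       with_structural=False)
cohort, truth = simulate_cohort(cfg)

res = ConnectomePredictiveModel(
    cohort, "macro_score",
    CPMConfig(n_perm_edge=200, n_perm_model=500,
              cv_folds=5, stability_frac=0.8)).fit()
print(res.summary())

aging = AgingTrendAnalysis(cohort, "macro_score", truth.hubs_macro,
                           n_perm=100, seed=1).fit()
print(aging.summary())

tp = estimate_turning_point(cohort.ages, cohort.score("macro_score"), seed=1)
print(tp.summary())
```

prints

```
Connectome-based predictive model
=============================================
score:            macro_score
status:           ok
validated edges:  82
train r:          0.950
test r:           0.952
permutation p:    0.001996
n train / test:   450 / 50

Sliding age-window narrative-coupling trends
==============================================
score:                 macro_score
edges tested:          339
windows:               size 30, mode sliding, step 1
significant edges:     42 (q < 0.05)
  compensatory (+):    20
  declining (-):       22

Turning point at 73.5 years (bootstrap 95% CI [69.3, 74.5]), slope change -0.099/yr, p = 0.00498
```

The CPM validates 82 edges (the 40 planted macro-signal edges are all among
them) and predicts the held-out macro score at r = 0.95; the window analysis
recovers exactly the 20 planted compensatory edges as positive (plus the 20
declining ones and 2 false labels); the change-point estimator lands near
the planted break at 72 years.

A `narraging` console script exposes the same stages
(`simulate`, `cpm`, `aging`, `behavior`, `run-all`) with YAML configuration:

```bash
narraging simulate --out cohort/ --seed 1
narraging cpm --score macro_score --cohort cohort/ --out model.json
narraging run-all --out results/ --seed 1
```

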