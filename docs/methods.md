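# Methods

## Overview

`trajectome` implements a pipeline for characterizing disease-trajectory
subtypes of a target disorder (the running example is major depressive
disorder, coded F32/F33) from first-onset histories:

1. **Relevance scoring** — which diseases carry direct (non-mediated)
   information about the target, per cumulative age interval, via the
   posterior probability of Markov-boundary membership in a dynamic Bayesian
   network (DBN).
2. **Trajectory scoring and clustering** — relevance-weighted multimorbidity
   scores per interval define a low-dimensional trajectory space in which
   participants are clustered with k-means; membership is soft.
3. **Cluster profiling** — posterior-weighted Cox and Kaplan-Meier models for
   disease outcomes, and linear models of membership log-odds on risk
   factors.
4. **Network pleiotropy** — propagation of gene-level evidence over an
   interactome, knee-point selection of top genes, spectral modules, and a
   degree-aware permutation test for target-signal enrichment per module.
5. **Subset evaluation** — clustering fidelity when only a disease subset is
   observable, with greedy forward selection and two membership null models.

All stages are exercised on a synthetic-cohort generator with planted ground
truth, since the real cohorts such analyses are run on are access-restricted.

## Cumulative-interval discretization

First onsets are coded on cumulative age intervals `[0, e_t]` with default
ends 20, 40, 60 and 70 years: `indicator[i, d, t] = 1` iff participant *i*'s
first onset of disease *d* occurred at or before `e_t`.  An onset falling
exactly on an interval end counts as inside (the interval is closed on the
right).  A participant contributes to interval *t* only if observed through
its end (`censor_age >= e_t`), which makes the inclusion mask monotone: a
participant observed through `e_t` is observed through every earlier end.

## Strong relevance in the dynamic Bayesian network

For each interval *t* a DBN is learned over the interval-*t* indicators plus
the interval-(t−1) indicators, the latter restricted to parent-only roles (no
edge may point into the past).  Disease *X* is *strongly relevant* to the
target *Y* in a structure *G* when *G* has an edge between *X* and *Y* in
either direction or *X* and *Y* share a common child — exactly the
Markov-boundary membership condition, which is invariant across
Markov-equivalent DAGs.  The posterior relevance is the expectation of this
indicator under the structure posterior.

Choices that the underlying method leaves open, and how this package fixes
them:

- **Scoring metric**: BDeu marginal likelihood with equivalent sample size
  1.0 and a uniform prior over constraint-respecting DAGs.  ESS is
  configurable.
- **Sampler**: Metropolis-coupled MCMC (MC³).  Proposals are drawn uniformly
  from the fixed enumeration of (add, delete, reverse) × (ordered node
  pairs); draws that would violate acyclicity, the parent limit (default 8)
  or the temporal constraint are rejected in place, which keeps the kernel
  symmetric and removes the need for neighbourhood-size Hastings
  corrections.  The default ladder is geometric with ratio 1.5 over 4
  chains; adjacent chains attempt a state swap every 100 steps.  The cold
  chain is recorded with thinning 10.
- **Per-disease aggregation**: a disease is counted as relevant in a sample
  if the indicator holds for *either* its interval-*t* or its
  interval-(t−1) node with respect to the interval-*t* target.
- **Target composite**: multiple target codes (e.g. F32 and F33) are merged
  into a single OR node per slice.
- **Degenerate variables**: all-constant columns are excluded from the
  candidate set with a warning.

The default sampler settings mirror a production run (burn-in 2×10⁶,
10⁷ collected structures); the test suite and the acceptance script use
reduced settings (burn-in 5×10³–10⁴, 3×10⁴–10⁵ samples, 3 chains, parent
limit 4), which the exact-enumeration comparisons show are already well
within 0.02 of the exact posterior on the panels those checks run on.

An **exact oracle** enumerates all constraint-respecting DAGs for panels with
at most 5 current-slice variables.  Prev-slice parent subsets cannot create
cycles, so they are marginalized analytically inside each node family
(including the per-prev-node inclusion probabilities needed for the
relevance indicator), and only within-slice edge configurations are
enumerated explicitly.  The oracle shares the scoring code with the sampler
but none of the sampling machinery.

**Convergence** is monitored with Geweke z-scores on the relevance-indicator
trace (first 10% vs last 50%, Bartlett-window spectral variances,
|z| ≤ 2 conventionally acceptable).  A fully constant trace is defined as
converged (z = 0); two constant segments with different means are flagged
(z = ±∞).

## Multimorbidity scores and soft clustering

The interval-*t* score of participant *i* sums the onset indicators of the
relevant diseases weighted by their cross-cohort relevance.  Cohort tables
are combined by a weighted mean (uniform by default) over the diseases
available in every cohort; diseases enter the relevant set when their
posterior exceeds 0.5 (strictly) in any interval of any cohort.

k-means (k-means++ initialization, 50 restarts, fixed seed, default k = 7)
is fit on participants with complete score vectors, i.e. those censored at
or after the last interval end.  Membership is soft:

- likelihood: `exp(-||p_i - c_j||)` (Euclidean distance),
- posterior: softmax of the negative distances,
- log-odds: `ln(P / (1 - P))`.

All three are computed in log space so extreme distances stay finite; the
posterior is strictly inside (0, 1) mathematically but may round to 0 or 1
in double precision when centre gaps exceed ~36 nats.  Participants with
partial score vectors are assigned using Euclidean distance on their
observed coordinates only, without rescaling by the dimension count (an
alternative normalized distance would reweight early-life information; the
raw form was chosen because the inclusion mask is monotone, so observed
coordinates are always a prefix of the interval axis).  Argmax ties break to
the lowest cluster index.  The confidence filter excludes participants who
are both under 60 years old and have maximum posterior ≤ 0.25.

**Federated fitting** never moves individual rows: each site floors its
complete score vectors onto a shared lattice (`floor(score / bin_width)`),
the integer bin counts are pooled, and count-weighted k-means runs on the
bin midpoints.  Bins are sorted lexicographically before fitting, so any
partition of the rows across sites yields byte-identical input and hence an
identical model; the quantization error of the centres is bounded by the
bin diagonal.

## Cluster profiling

**Weighted Cox.**  Every participant enters each per-cluster model twice:
dummy = 1 with weight `P_j(i)` and dummy = 0 with weight `1 - P_j(i)` (rows
sum to weight 1; zero-weight rows are dropped, so degenerate 0/1 posteriors
reduce the design to the plain hard-label model).  Time axis is age;
participants without the outcome are right-censored at their censoring age.
Ties use the Efron approximation; the CI is Wald on the log scale, with
sandwich standard errors available (`robust=True`).  Covariates default to
sex, income and the z-scored birth year.  P-values are Benjamini-Hochberg
adjusted within cohort.  Note the weighting scheme is a heuristic: with soft
(non-degenerate) posteriors the dummy coefficient is attenuated toward zero
relative to the true group contrast, which is why frequentist coverage of a
planted hazard ratio is checked with known membership.

**Weighted Kaplan-Meier** uses the posterior as a case weight in the
product-limit estimator; the curve is invariant to uniform weight scaling.

**Risk-factor regressions** model the standardized posterior log-odds per
cluster.  Age enters as a cubic B-spline with interior knots at 40 and 60
years; a knot outside the observed age span is dropped (single-knot
fallback).  "Simple" mode fits one factor at a time with age and sex on
complete cases; "complex" mode fits all factors jointly after k-nearest-
neighbour imputation (k = 5).  Continuous variables are standardized, tests
are two-sided t-tests, and Bonferroni adjustment runs over factor × cluster.

## Network pleiotropy

RWR/personalized PageRank solves `s = r·e + (1-r)·W s` with column-normalized
adjacency, seed distribution `e` normalized to sum 1, restart `r = 0.5` by
default, and power iteration to 1e-10; zero-degree nodes get a self-loop so
restart mass on them is conserved.  Scores therefore always sum to 1.

The top-gene cut uses Kneedle: both axes normalized to [0, 1], knee at the
maximum difference between the chord and the curve; when that maximum does
not exceed `sensitivity/(n-1)` (a straight line) no knee is declared and the
caller falls back to a quantile.  Modules come from normalized-Laplacian
spectral embedding plus k-means; the module count defaults to the largest
eigengap, capped at √(subgraph size).

The module statistic is the sum of RWR scores (seeded from the
target-disease genes) over module genes.  The null redistributes seed genes
uniformly *without replacement* within logarithmic degree bins (factor 2),
preserving hubness; `p = (1 + #{null ≥ observed}) / (B + 1)`.  All B
permuted seed vectors propagate in one batched power iteration.  One
consequence of degree-aware permutation worth knowing: when the seeded
region and many degree-matched alternatives are symmetric (e.g. two equal
cliques), the probability that a permutation reproduces the observed
configuration is bounded below by a combinatorial term, so very small
p-values require enough degree-matched placements outside the tested module.

## Subset evaluation

Scores are recomputed from the subset alone and participants reassigned with
the *frozen* full-set centres.  Dropping diseases shrinks scores toward the
origin, so subsets that keep whole marker groups (preserving the calibrated
magnitude of some score dimensions) outperform size-matched subsets that
thin every group — visible in the test suite.  Metrics: hard-label accuracy
and balanced accuracy, MAE and MSE of posterior vectors, averaged over
repeated draws (defaults: 10,000 participants × 100 repeats; tests use
smaller draws).  Greedy forward selection adds the accuracy-maximizing
disease each step, ties broken by code order; it is not guaranteed optimal
beyond the first step.  The "random" null draws memberships from
Dirichlet(1, ..., 1) — any exchangeable choice yields 1/k expected accuracy,
which for k = 7 is the ~14% baseline — and the "uniform" null predicts the
constant 1/k vector with a randomized hard label.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular biobank:

- latent trajectory clusters with mixture weights;
- piecewise-constant onset hazards per age band with per-cluster
  multipliers; first-event times sampled by inversion, the last band's rate
  extending beyond the final interval end;
- a target disease whose hazard is multiplied by `exp(parent_effect)` once
  any *direct parent* disease has onset, and a *mediator* whose hazard
  responds to the *mediated* diseases the same way;
- heterogeneous uniform censoring ages, and covariates: sex ~ Bernoulli(0.5),
  3-level income, uniform birth years.

Parent effects switch on at the next age-band boundary rather than
instantaneously.  Because the DBN only sees band-level indicators, this
makes mediated diseases *exactly* conditionally independent of the target
given the mediator's band history (verified by a stratified
Cochran-Mantel-Haenszel test), so the planted direct/mediated distinction is
recoverable in principle.  Continuous-time switching would leak
within-interval timing and blur the distinction at large n.

Two canonical configurations define the study conditions:

- `markov_boundary_config`: one latent cluster, two direct parents (one the
  mediator), two mediated and one irrelevant disease, band hazards giving
  tens-of-percent prevalences by age 70, log-hazard effects 1.5, censoring
  uniform on [60, 80].  A single cluster is essential: a shared latent
  cluster multiplier would confound every disease with the target and
  place mediated diseases in the target's *observational* Markov boundary.
- `well_separated_trajectory_config`: 7 clusters built from five groups of 8
  marker diseases, each group's hazard concentrated in one age band
  (within-band onset probability 0.97 when active, background multiplier
  0.01); clusters switch different group combinations on, so expected score
  trajectories are pairwise at least one full group (8 units) apart against
  a within-cluster standard deviation near 1 — the ≥6-sigma separation
  regime.  Censoring uniform on [50, 85] leaves roughly 43% of participants
  fully observed.

What the generator does *not* emulate: calendar-time and cohort effects,
diagnostic code noise and ICD hierarchy, recurrent episodes (first onsets
only), informative censoring, and genotypes (gene scores are drawn directly:
background p-values uniform on (0, 1], signal genes pushed toward a 1e-8
floor by a power transform).  Interactomes are planted-partition graphs, not
curated protein networks.  Passing tests therefore demonstrate that the
estimators recover what they are defined to recover under the assumed
structure — not robustness to the many ways real EHR and GWAS data violate
it.

## Problem sizes and numerics

The test suite and acceptance script run at: n = 2,000 for
oracle-vs-sampler comparisons (tolerance 0.02 at 10⁵ samples), n = 20,000 ×
20 seeds for Markov-boundary discrimination, n = 10,000 for cluster
recovery (ARI computed on the fully observed participants, whose labels are
identifiable; young participants' trajectories have not yet diverged),
n = 20,000 × 50 seeds for Cox CI coverage, 1,000 module tests at B = 99 for
permutation-null calibration.  These sizes were chosen so each Monte-Carlo
check has comfortable resolution for the property it asserts.

Numerical conventions: posterior/log-odds computed via shifted log-sum-exp;
relevance posteriors clipped to [0, 1] against round-off; k-means
determinism via fixed `random_state` and sorted federated bins; permutation
p-values floored at 1/(B+1); BDeu scores handle empty data as the empty
product (score 0 for every structure, i.e. the prior).

## Known limitations

- The duplicated-row weighted Cox estimand is attenuated under soft
  posteriors (see above); it profiles clusters rather than estimating a
  causal contrast.
- Greedy subset selection is a heuristic; only its first step is provably
  optimal.
- The exact relevance oracle is limited to 5 current-slice variables;
  beyond that only MCMC (with Geweke monitoring) is available.
- Relevance aggregation assumes cohorts share the discretization grid;
  heterogeneous grids are rejected rather than harmonized.
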