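# trajectome

Multimorbidity **trajectory clustering** for a target disorder, built around
three statistical ideas:

1. **Markov-boundary relevance.** For each cumulative age interval
   `[0, e_t]` (defaults: 20, 40, 60, 70 years) a dynamic Bayesian network is
   learned over binary first-onset indicators, with interval-(t−1) copies of
   every disease restricted to parent roles.  A disease *X* is *strongly
   relevant* to the target *Y* when the sampled structure has an edge
   between *X* and *Y* or a common child — Markov-boundary membership:

       P(strongly-relevant(X, Y) | D)
           = Σ_G P(G | D) · I( X→Y or Y→X or ∃Z: X→Z and Y→Z in G )

   estimated by Metropolis-coupled structure MCMC under a BDeu score, with
   an exact DAG-enumeration oracle for small panels.  Unlike a pairwise
   association, this score screens out diseases whose link to the target is
   mediated by a third disease.

2. **Soft trajectory clustering.** Relevance-weighted multimorbidity scores

       score_t(i) = Σ_d 1[onset(i, d) ≤ e_t] · relevance_t(d)

   place each participant in a T-dimensional trajectory space, clustered by
   k-means on the fully observed participants (k = 7 by default).
   Membership is soft: likelihood `exp(−‖p_i − c_j‖)`, posterior
   `P_j(i) = softmax_j(−‖p_i − c_j‖)`, log-odds `ln(P_j / (1 − P_j))`.
   Partially observed participants are assigned on their observed
   coordinates; a count-based federated mode fits the same model from
   per-site bin counts without moving individual rows.

3. **Cluster profiling and downstream structure.**  Posterior-weighted Cox
   and Kaplan-Meier models give per-cluster disease profiles; linear models
   of the membership log-odds profile risk factors; random-walk-with-restart
   propagation over an interactome plus a degree-aware permutation test
   quantifies module-level pleiotropy; and greedy subset selection measures
   how well reduced disease sets reproduce the full clustering.

Real cohorts for such analyses are access-restricted, so the package ships a
synthetic-cohort generator with planted ground truth (latent clusters,
piecewise-constant band hazards, direct-parent and mediated disease effects,
right-censoring) that every stage is tested against.

## Worked example

```python
import pandas as pd
from trajectome import (
    McmcSettings, RelevanceTable, assign, discretize, fit_clusters,
    generate_cohort, mcmc_sample, multimorbidity_scores,
    strong_relevance_posterior,
)
from trajectome.synthetic_cohort import (
    markov_boundary_config, well_separated_trajectory_config,
)

# --- which diseases are strongly relevant to the target?
cohort, truth = generate_cohort(markov_boundary_config(20_000, seed=0))
panel = discretize(cohort)
settings = McmcSettings(burn_in=5_000, n_samples=30_000, n_chains=3,
                        max_parents=4, seed=1)
trace = mcmc_sample(panel, "F32", interval=2, settings=settings)
print(strong_relevance_posterior(trace).round(3))
```

```
D01    1.0
D02    1.0
M01    0.0
M02    0.0
R01    0.0
```

The planted direct parents (`D01`, `D02`) get posterior relevance 1 and
clear the 0.5 selection cutoff; the mediated diseases (`M01`, `M02`), which
are *marginally* associated with the target through the mediator `D01`, and
the irrelevant disease `R01` are correctly screened out.

```python
# --- cluster trajectories and recover the planted structure
cohort, truth = generate_cohort(well_separated_trajectory_config(10_000, seed=0))
panel = discretize(cohort)
codes = [c for c in panel.codes if c != "F32"]
weights = RelevanceTable.constant(codes, panel.grid.interval_ends, 1.0)
scores = multimorbidity_scores(panel.restrict(codes), weights)
model = fit_clusters(scores, k=7, seed=0)
memberships = assign(scores, model)
print(memberships[["posterior_1", "hard_label"]].head(3).round(3))

from sklearn.metrics import adjusted_rand_score
complete = scores.dropna().index
labels = pd.Series(truth.labels, index=panel.participants)
print("ARI:", round(adjusted_rand_score(labels.loc[complete],
                                        memberships.loc[complete, "hard_label"]), 3))
```

```
         posterior_1  hard_label
P000000          0.0           7
P000001          0.0           2
P000002          0.0           4
ARI: 0.996
```

The k-means model, fit on the ~43% of participants observed through age 70,
recovers the seven planted trajectory clusters nearly perfectly (adjusted
Rand index 0.996 against the generator's labels).

See `docs/methods.md` for the model details, the generator's design and its
limitations, and all numerical conventions.

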