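"""Multimorbidity scores, soft trajectory clustering and federated fitting.

Per participant i and cumulative interval t the weighted multimorbidity score
sums the onset indicators over the relevant diseases, weighted by their
cross-cohort relevance:

    score_t(i) = sum_d 1[onset(i, d) <= e_t] * relevance_t(d).

The T-dimensional score vectors of fully observed participants (censored at
or after the last interval end) are clustered with k-means.  Membership is
soft: likelihood_j(i) = exp(-||p_i - c_j||), the posterior is its
normalization over clusters (a softmax of negative Euclidean distances) and
the log-odds is the posterior's logit.  Participants with incomplete score
vectors are assigned on their observed coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .bn_relevance import RelevanceTable
from .cohort_io import IntervalPanel


class ClusterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Relevance aggregation and disease selection
# ---------------------------------------------------------------------------


def cross_cohort_scores(
    per_cohort: list[RelevanceTable], weights: list[float] | None = None
) -> RelevanceTable:
    """Weighted mean of cohort relevance tables on the diseases available in
    every cohort (uniform weights by default)."""
    if not per_cohort:
        raise ClusterError("need at least one cohort table")
    if weights is None:
        weights = [1.0 / len(per_cohort)] * len(per_cohort)
    if len(weights) != len(per_cohort) or abs(sum(weights) - 1.0) > 1e-9:
        raise ClusterError("weights must match cohorts and sum to 1")
    cols = list(per_cohort[0].scores.columns)
    for t in per_cohort[1:]:
        if list(t.scores.columns) != cols:
            raise ClusterError("cohort tables have mismatched intervals")
    common = sorted(
        set.intersection(*(set(t.scores.index) for t in per_cohort))
    )
    acc = sum(
        w * t.scores.loc[common] for w, t in zip(weights, per_cohort)
    )
    return RelevanceTable(scores=acc, provenance="cross-cohort")


def select_diseases(
    tables: list[RelevanceTable], cutoff: float = 0.5
) -> list[str]:
    """Diseases whose relevance strictly exceeds ``cutoff`` in at least one
    interval of at least one cohort, restricted to diseases available in all
    cohorts."""
    if not 0 < cutoff < 1:
        raise ClusterError("cutoff must be in (0, 1)")
    common = set.intersection(*(set(t.scores.index) for t in tables))
    selected = set()
    for t in tables:
        hits = t.scores.loc[sorted(common & set(t.scores.index))]
        mask = (hits.to_numpy() > cutoff).any(axis=1)
        selected |= set(hits.index[mask])
    return sorted(selected)


# ---------------------------------------------------------------------------
# Score matrix
# ---------------------------------------------------------------------------


def multimorbidity_scores(
    panel: IntervalPanel, relevance: RelevanceTable
) -> pd.DataFrame:
    """Per-participant, per-interval weighted multimorbidity scores.

    Returns a DataFrame indexed by participant with one column per interval
    end; entries are NaN where the participant is not observed through the
    interval.  Every panel disease must appear in the relevance table.
    """
    missing = [c for c in panel.codes if c not in relevance.scores.index]
    if missing:
        raise ClusterError(f"diseases missing from relevance table: {missing[:5]}")
    ends = list(panel.grid.interval_ends)
    rel = relevance.scores.loc[panel.codes, ends].to_numpy(dtype=float)  # (d, T)
    scores = np.einsum("ndt,dt->nt", panel.indicators.astype(float), rel)
    scores[~panel.included] = np.nan
    return pd.DataFrame(scores, index=panel.participants, columns=ends)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    centres: np.ndarray  # (k, T)
    interval_ends: tuple[float, ...]
    inertia: float
    silhouette: float | None
    seed: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or not np.all(np.isfinite(self.centres)):
            raise ClusterError("invalid cluster model")


def fit_clusters(
    scores: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    n_init: int = 50,
    silhouette_subsample: int = 5000,
) -> ClusterModel:
    """k-means on the participants with complete score vectors, best of
    ``n_init`` k-means++ restarts by inertia; reports a (subsampled)
    silhouette score as a fit diagnostic."""
    complete = scores.dropna()
    if len(complete) < k:
        raise ClusterError(f"need at least k={k} complete-score participants")
    x = complete.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    sil = None
    if k > 1 and len(np.unique(labels)) > 1:
        if len(x) > silhouette_subsample:
            idx = np.random.default_rng(seed).choice(
                len(x), silhouette_subsample, replace=False
            )
            sub_x, sub_l = x[idx], labels[idx]
        else:
            sub_x, sub_l = x, labels
        if len(np.unique(sub_l)) > 1:
            sil = float(silhouette_score(sub_x, sub_l))
    inertia = float(km.inertia_)
    return ClusterModel(
        k=k,
        centres=km.cluster_centers_,
        interval_ends=tuple(scores.columns),
        inertia=inertia,
        silhouette=sil,
        seed=seed,
        degenerate=inertia == 0.0,
    )


def _membership_from_distances(dist: np.ndarray) -> tuple[np.ndarray, ...]:
    """likelihood exp(-d), posterior softmax(-d) and its logit, all computed
    in log space so extreme distances stay finite."""
    neg = -dist
    log_z = logsumexp(neg, axis=1, keepdims=True)
    log_post = neg - log_z
    post = np.exp(log_post)
    # log(1 - P_j) via the complementary log-sum-exp, stable when P_j ~ 1
    k = dist.shape[1]
    log_not = np.empty_like(log_post)
    for j in range(k):
        others = np.delete(neg, j, axis=1)
        log_not[:, j] = logsumexp(others, axis=1) - log_z[:, 0]
    logodds = log_post - log_not
    likelihood = np.exp(neg)
    return likelihood, post, logodds


def assign(scores: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Soft cluster memberships for every participant with at least one
    observed score.

    Distances for partially observed participants use the observed
    coordinates only (no rescaling).  Returns a MembershipTable DataFrame
    with likelihood_j, posterior_j, logodds_j columns, the hard label
    (1-based argmax, ties to the lowest index) and the observed-dimension
    count.
    """
    x = scores.to_numpy(dtype=float)
    observed = ~np.isnan(x)
    if (observed.sum(axis=1) == 0).any():
        raise ClusterError("participant with zero observed score coordinates")
    n, k = len(x), model.k
    dist = np.zeros((n, k))
    # inclusion is monotone, so there are at most T distinct patterns
    patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = inverse == pi
        sub = x[np.ix_(rows, pat)]
        cent = model.centres[:, pat]
        d2 = ((sub[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        dist[rows] = np.sqrt(d2)
    likelihood, post, logodds = _membership_from_distances(dist)
    hard = post.argmax(axis=1) + 1
    out = {}
    for j in range(k):
        out[f"likelihood_{j + 1}"] = likelihood[:, j]
    for j in range(k):
        out[f"posterior_{j + 1}"] = post[:, j]
    for j in range(k):
        out[f"logodds_{j + 1}"] = logodds[:, j]
    frame = pd.DataFrame(out, index=scores.index)
    frame["hard_label"] = hard
    frame["n_observed"] = observed.sum(axis=1)
    return frame


def posterior_matrix(memberships: pd.DataFrame) -> np.ndarray:
    cols = sorted(
        (c for c in memberships.columns if c.startswith("posterior_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return memberships[cols].to_numpy(dtype=float)


def logodds_matrix(memberships: pd.DataFrame) -> np.ndarray:
    cols = sorted(
        (c for c in memberships.columns if c.startswith("logodds_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return memberships[cols].to_numpy(dtype=float)


def confidence_filter(
    memberships: pd.DataFrame, ages: pd.Series, age_cutoff: float = 60.0,
    posterior_cutoff: float = 0.25
) -> pd.Series:
    """Inclusion mask: excluded iff younger than ``age_cutoff`` AND the
    maximum posterior does not exceed ``posterior_cutoff``."""
    post = posterior_matrix(memberships)
    max_post = post.max(axis=1)
    age = ages.loc[memberships.index].to_numpy(dtype=float)
    include = ~((age < age_cutoff) & (max_post <= posterior_cutoff))
    return pd.Series(include, index=memberships.index, name="included")


# ---------------------------------------------------------------------------
# Federated fitting from binned counts
# ---------------------------------------------------------------------------


def federated_fit(
    site_scores: list[pd.DataFrame],
    bin_width: float,
    k: int = 7,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterModel:
    """Privacy-preserving k-means: each site quantizes its complete score
    vectors onto a shared lattice and reports bin counts only; the pooled
    counts are clustered with count-weighted k-means on the bin midpoints.
    """
    if bin_width <= 0:
        raise ClusterError("bin_width must be positive")
    if not site_scores:
        raise ClusterError("need at least one site")
    cols = list(site_scores[0].columns)
    counts: dict[tuple[int, ...], float] = {}
    for site in site_scores:
        if list(site.columns) != cols:
            raise ClusterError("sites have incompatible time grids")
        complete = site.dropna().to_numpy(dtype=float)
        bins = np.floor(complete / bin_width).astype(np.int64)
        for key in map(tuple, bins):
            counts[key] = counts.get(key, 0.0) + 1.0
    keys = sorted(counts)
    midpoints = (np.asarray(keys, dtype=float) + 0.5) * bin_width
    weights = np.asarray([counts[key] for key in keys])
    if len(keys) < k:
        raise ClusterError("fewer occupied bins than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(midpoints, sample_weight=weights)
    return ClusterModel(
        k=k,
        centres=km.cluster_centers_,
        interval_ends=tuple(cols),
        inertia=float(km.inertia_),
        silhouette=None,
        seed=seed,
    )
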