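"""Clustering fidelity under reduced disease sets.

When only a subset of the relevant diseases is observable, the
multimorbidity scores are recomputed from the subset alone and participants
are reassigned with the *original* cluster centres.  Performance against the
full-set reference is summarized by four measures: accuracy and balanced
accuracy of the hard labels, and the mean absolute / mean squared error of
the posterior membership vectors, averaged over repeated random draws of
participants.  Greedy forward selection expands the subset one disease at a
time, always adding the accuracy-maximizing disease; two null models (random
simplex memberships and the constant uniform membership) calibrate the
scale of the measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score

from .bn_relevance import RelevanceTable
from .cluster_engine import ClusterModel, assign, multimorbidity_scores, posterior_matrix
from .cohort_io import IntervalPanel


class SubsetError(ValueError):
    pass


@dataclass
class SubsetPerformance:
    subset: tuple[str, ...]
    accuracy: float
    balanced_accuracy: float
    mae: float
    mse: float
    n_evaluated: int
    n_repeats: int


def _metrics(
    ref_hard: np.ndarray,
    ref_post: np.ndarray,
    sub_hard: np.ndarray,
    sub_post: np.ndarray,
    sample_size: int,
    n_repeats: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float, int]:
    n = len(ref_hard)
    size = min(sample_size, n)
    accs, baccs, maes, mses = [], [], [], []
    for _ in range(n_repeats):
        idx = rng.choice(n, size=size, replace=False)
        accs.append(float(np.mean(ref_hard[idx] == sub_hard[idx])))
        baccs.append(float(balanced_accuracy_score(ref_hard[idx], sub_hard[idx])))
        err = sub_post[idx] - ref_post[idx]
        maes.append(float(np.abs(err).mean()))
        mses.append(float((err**2).mean()))
    return (
        float(np.mean(accs)),
        float(np.mean(baccs)),
        float(np.mean(maes)),
        float(np.mean(mses)),
        size,
    )


def evaluate_subset(
    subset: list[str],
    reference: pd.DataFrame,
    panel: IntervalPanel,
    relevance: RelevanceTable,
    model: ClusterModel,
    sample_size: int = 10_000,
    n_repeats: int = 100,
    seed: int = 0,
    allow_empty: bool = False,
) -> SubsetPerformance:
    """Recompute scores from ``subset`` diseases only, reassign with the
    frozen full-set centres, and compare against the full-set reference
    memberships."""
    if not subset and not allow_empty:
        raise SubsetError("empty subset (allowed only for null baselines)")
    unknown = set(subset) - set(relevance.scores.index)
    if unknown:
        raise SubsetError(f"subset diseases without relevance: {sorted(unknown)[:5]}")
    if subset:
        sub_panel = panel.restrict(list(subset))
        scores = multimorbidity_scores(sub_panel, relevance)
    else:
        ends = list(panel.grid.interval_ends)
        scores = pd.DataFrame(
            np.where(panel.included, 0.0, np.nan),
            index=panel.participants,
            columns=ends,
        )
    memberships = assign(scores, model).loc[reference.index]
    rng = np.random.default_rng(seed)
    acc, bacc, mae, mse, n_eval = _metrics(
        reference["hard_label"].to_numpy(),
        posterior_matrix(reference),
        memberships["hard_label"].to_numpy(),
        posterior_matrix(memberships),
        sample_size,
        n_repeats,
        rng,
    )
    return SubsetPerformance(
        subset=tuple(subset),
        accuracy=acc,
        balanced_accuracy=bacc,
        mae=mae,
        mse=mse,
        n_evaluated=n_eval,
        n_repeats=n_repeats,
    )


def greedy_select(
    diseases: list[str],
    reference: pd.DataFrame,
    panel: IntervalPanel,
    relevance: RelevanceTable,
    model: ClusterModel,
    budget: int,
    sample_size: int = 10_000,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[list[str], list[SubsetPerformance]]:
    """Greedy forward selection: each step adds the disease maximizing the
    hard-label accuracy against the full-set reference (ties broken by
    disease-code order).  Greedy is not guaranteed optimal beyond step 1.
    """
    if budget < 1:
        raise SubsetError("budget must be at least 1")
    if budget > len(diseases):
        raise SubsetError("budget exceeds available diseases")
    chosen: list[str] = []
    curve: list[SubsetPerformance] = []
    remaining = sorted(diseases)
    for _ in range(budget):
        best_perf = None
        best_code = None
        for code in remaining:
            perf = evaluate_subset(
                chosen + [code],
                reference,
                panel,
                relevance,
                model,
                sample_size=sample_size,
                n_repeats=n_repeats,
                seed=seed,
            )
            if best_perf is None or perf.accuracy > best_perf.accuracy:
                best_perf, best_code = perf, code
        chosen.append(best_code)
        remaining.remove(best_code)
        curve.append(best_perf)
    return chosen, curve


def null_performance(
    model: ClusterModel,
    reference: pd.DataFrame,
    kind: str = "random",
    sample_size: int = 10_000,
    n_repeats: int = 100,
    seed: int = 0,
) -> SubsetPerformance:
    """Null baselines: ``random`` draws membership vectors uniformly from the
    probability simplex (Dirichlet(1, ..., 1)) and hard-assigns by argmax;
    ``uniform`` predicts the constant 1/k vector with a randomized hard
    label."""
    if kind not in ("random", "uniform"):
        raise SubsetError("kind must be 'random' or 'uniform'")
    rng = np.random.default_rng(seed)
    k = model.k
    n = len(reference)
    ref_hard = reference["hard_label"].to_numpy()
    ref_post = posterior_matrix(reference)
    if kind == "random":
        post = rng.dirichlet(np.ones(k), size=n)
        hard = post.argmax(axis=1) + 1
    else:
        post = np.full((n, k), 1.0 / k)
        hard = rng.integers(1, k + 1, size=n)
    acc, bacc, mae, mse, n_eval = _metrics(
        ref_hard, ref_post, hard, post, sample_size, n_repeats, rng
    )
    return SubsetPerformance(
        subset=(),
        accuracy=acc,
        balanced_accuracy=bacc,
        mae=mae,
        mse=mse,
        n_evaluated=n_eval,
        n_repeats=n_repeats,
    )


def performance_curve_frame(
    order: list[str], curve: list[SubsetPerformance]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": np.arange(1, len(curve) + 1),
            "disease_added": order,
            "accuracy": [c.accuracy for c in curve],
            "balanced_accuracy": [c.balanced_accuracy for c in curve],
            "mae": [c.mae for c in curve],
            "mse": [c.mse for c in curve],
        }
    )
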