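"""Module-level pleiotropy on an interactome via network propagation.

Gene-level evidence (-log adjusted p-values) for a cluster is propagated over
the protein interaction network with random walk with restart (personalized
PageRank), the top-scoring genes are cut by the Kneedle knee of the sorted
score curve, and their induced subgraph is split into non-overlapping modules
by spectral clustering.  Each module is then tested for enrichment of
propagated *target-disease* signal against a degree-aware permutation null
that reassigns seed genes within logarithmic degree bins, preserving hubness.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans


class PleiotropyError(ValueError):
    pass


@dataclass
class ModuleResult:
    module_id: int
    genes: frozenset[str]
    statistic: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None


def evidence_scores(gene_scores: pd.DataFrame) -> pd.Series:
    """-log adjusted p-value per gene (nonnegative evidence)."""
    p = gene_scores.set_index("gene_id")["p_adj"]
    if ((p <= 0) | (p > 1)).any():
        raise PleiotropyError("adjusted p-values must lie in (0, 1]")
    return -np.log(p)


def _transition_matrix(network: nx.Graph, nodes: list[str]) -> sp.csr_matrix:
    """Column-normalized adjacency; zero-degree nodes are given a self-loop so
    restart mass on them is conserved."""
    a = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(a.sum(axis=0)).ravel()
    isolated = np.flatnonzero(deg == 0)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    w = a @ sp.diags(inv)
    if len(isolated):
        w = w.tolil()
        for j in isolated:
            w[j, j] = 1.0
        w = w.tocsc()
    return sp.csr_matrix(w)


def _seed_vector(
    seeds: pd.Series | dict[str, float], nodes: list[str]
) -> np.ndarray:
    seeds = pd.Series(seeds, dtype=float)
    if len(seeds) == 0:
        raise PleiotropyError("empty seed set")
    unknown = set(seeds.index) - set(nodes)
    if unknown:
        raise PleiotropyError(f"seed genes not in network: {sorted(unknown)[:5]}")
    if (seeds < 0).any() or seeds.sum() <= 0:
        raise PleiotropyError("seed weights must be nonnegative with positive sum")
    e = np.zeros(len(nodes))
    pos = {g: i for i, g in enumerate(nodes)}
    for g, v in seeds.items():
        e[pos[g]] = v
    return e / e.sum()


def _rwr_solve(
    w: sp.csr_matrix,
    e: np.ndarray,
    restart: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Power iteration for s = restart*e + (1-restart) W s; ``e`` may hold one
    seed distribution per column."""
    s = e.copy()
    for _ in range(max_iter):
        nxt = restart * e + (1.0 - restart) * (w @ s)
        if np.abs(nxt - s).max() < tol:
            return nxt
        s = nxt
    return s


def rwr(
    network: nx.Graph,
    seeds: pd.Series | dict[str, float],
    restart: float = 0.5,
    tol: float = 1e-10,
) -> pd.Series:
    """Random walk with restart from a normalized seed distribution.

    Scores solve s = restart*e + (1-restart) W^T s with column-normalized
    adjacency W and sum to 1; ``restart=1`` returns the seed vector itself.
    """
    if not 0 < restart <= 1:
        raise PleiotropyError("restart must be in (0, 1]")
    nodes = sorted(network.nodes)
    if not nodes:
        raise PleiotropyError("empty network")
    e = _seed_vector(seeds, nodes)
    if restart == 1.0:
        return pd.Series(e, index=nodes, name="rwr")
    w = _transition_matrix(network, nodes)
    s = _rwr_solve(w, e, restart, tol)
    return pd.Series(s, index=nodes, name="rwr")


def kneedle_cutoff(
    sorted_scores: np.ndarray, sensitivity: float = 1.0
) -> int | None:
    """Knee index of a descending score curve (Kneedle).

    Both axes are normalized to [0, 1]; the knee is the argmax of the
    difference between the chord and the curve.  Returns None when the
    maximum difference does not exceed ``sensitivity / (n - 1)`` (e.g. for a
    straight line), signalling the caller to fall back to a quantile cut.
    """
    y = np.asarray(sorted_scores, dtype=float)
    n = len(y)
    if n < 3:
        raise PleiotropyError("need at least 3 scores")
    if np.any(np.diff(y) > 1e-12):
        raise PleiotropyError("scores must be sorted in descending order")
    span = y[0] - y[-1]
    if span == 0:
        return None
    x_norm = np.arange(n) / (n - 1)
    y_norm = (y - y[-1]) / span
    diff = (1.0 - x_norm) - y_norm
    knee = int(np.argmax(diff))
    if diff[knee] <= sensitivity / (n - 1):
        return None
    return knee


def spectral_modules(
    subgraph: nx.Graph, n_modules: int | None = None, seed: int = 0
) -> list[ModuleResult]:
    """Non-overlapping modules by normalized-Laplacian spectral embedding plus
    k-means; the module count defaults to the largest eigengap, capped at
    sqrt(number of genes)."""
    nodes = sorted(subgraph.nodes)
    n = len(nodes)
    if n == 0:
        raise PleiotropyError("empty subgraph")
    if n_modules is not None and n_modules > n:
        raise PleiotropyError("n_modules exceeds node count")
    if n == 1 or n_modules == 1:
        return [ModuleResult(module_id=1, genes=frozenset(nodes))]
    a = nx.to_scipy_sparse_array(subgraph, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    d_half = sp.diags(inv_sqrt)
    lap = sp.identity(n) - d_half @ a @ d_half
    k_eval = min(n - 1, max(2, int(np.ceil(np.sqrt(n))) + 1))
    if n <= 64:
        vals, vecs = np.linalg.eigh(lap.toarray())
        vals, vecs = vals[: k_eval + 1], vecs[:, : k_eval + 1]
    else:
        vals, vecs = eigsh(lap.tocsc(), k=k_eval + 1, sigma=-1e-6, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    if n_modules is None:
        gaps = np.diff(vals[: k_eval + 1])
        n_modules = int(np.argmax(gaps[1:]) + 2)  # skip the trivial first gap
        n_modules = min(n_modules, int(np.ceil(np.sqrt(n))))
        n_modules = max(2, min(n_modules, n))
    emb = vecs[:, :n_modules]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    labels = KMeans(n_clusters=n_modules, n_init=20, random_state=seed).fit_predict(emb)
    modules = []
    for m in range(n_modules):
        genes = frozenset(nodes[i] for i in np.flatnonzero(labels == m))
        if genes:
            modules.append(ModuleResult(module_id=len(modules) + 1, genes=genes))
    return modules


def _degree_bins(network: nx.Graph, factor: float = 2.0) -> dict[str, int]:
    """Logarithmic degree bins (bin b holds degrees in [factor^b, factor^(b+1));
    degree-0 nodes get their own bin)."""
    bins = {}
    for node, deg in network.degree():
        bins[node] = -1 if deg == 0 else int(np.floor(np.log(deg) / np.log(factor)))
    return bins


def module_pleiotropy_test(
    modules: list[ModuleResult],
    network: nx.Graph,
    target_seeds: pd.Series | dict[str, float],
    restart: float = 0.5,
    n_permutations: int = 999,
    seed: int = 0,
    degree_bin_factor: float = 2.0,
    tol: float = 1e-10,
) -> list[ModuleResult]:
    """Test each module for excess propagated target signal.

    The statistic is the sum over module genes of the RWR score seeded from
    the target genes; the null redistributes the seed genes uniformly within
    their logarithmic degree bins (without replacement) and the p-value is
    (1 + #{null >= observed}) / (B + 1).
    """
    if n_permutations < 1:
        raise PleiotropyError("need at least one permutation")
    nodes = sorted(network.nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    e_obs = _seed_vector(target_seeds, nodes)
    w = _transition_matrix(network, nodes)
    rng = np.random.default_rng(seed)

    bins = _degree_bins(network, degree_bin_factor)
    bin_members: dict[int, list[str]] = {}
    for node, b in bins.items():
        bin_members.setdefault(b, []).append(node)
    for b in bin_members:
        bin_members[b].sort()
    seed_series = pd.Series(target_seeds, dtype=float)
    seed_genes = list(seed_series.index)

    e_null = np.zeros((len(nodes), n_permutations))
    for perm in range(n_permutations):
        weights = np.zeros(len(nodes))
        by_bin: dict[int, list[str]] = {}
        for g in seed_genes:
            by_bin.setdefault(bins[g], []).append(g)
        for b, genes in by_bin.items():
            members = bin_members[b]
            picked = rng.choice(len(members), size=len(genes), replace=False)
            for g, m in zip(genes, picked):
                weights[pos[members[m]]] += seed_series[g]
        e_null[:, perm] = weights / weights.sum()

    if restart == 1.0:
        scores = np.column_stack([e_obs, e_null])
    else:
        scores = _rwr_solve(
            w, np.column_stack([e_obs, e_null]), restart, tol
        )
    obs_scores = scores[:, 0]
    null_scores = scores[:, 1:]
    results = []
    for module in modules:
        idx = [pos[g] for g in sorted(module.genes)]
        observed = float(obs_scores[idx].sum())
        null = null_scores[idx].sum(axis=0)
        p = float((1 + np.sum(null >= observed)) / (n_permutations + 1))
        results.append(
            ModuleResult(
                module_id=module.module_id,
                genes=module.genes,
                statistic=observed,
                p_value=p,
                n_permutations=n_permutations,
            )
        )
    return results


def module_results_frame(results: list[ModuleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [r.module_id for r in results],
            "n_genes": [len(r.genes) for r in results],
            "genes": [",".join(sorted(r.genes)) for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
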