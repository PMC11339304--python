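"""Markov-boundary relevance of diseases to a target via structure MCMC.

For each cumulative age interval t an inhomogeneous dynamic Bayesian network
is learned over the binary onset indicators: the interval-t copies of the
diseases (and optional covariates) are ordinary nodes, while the interval-
(t-1) copies may only act as parents.  A disease X is *strongly relevant* to
the target Y (equivalently, in Y's Markov boundary) in a structure G when G
contains an edge between X and Y in either direction, or X and Y share a
common child.  The posterior probability of strong relevance is the expected
value of that indicator under the structure posterior P(G | D),

    P(strongly-relevant(X, Y) | D)
        = sum_G P(G | D) * I(X~Y adjacent or common child in G),

estimated here by Metropolis-coupled MCMC over DAGs (add/delete/reverse edge
moves, parallel tempered chains with state swaps) under a BDeu marginal
likelihood with a uniform structure prior, and computed exactly by DAG
enumeration on small instances as an oracle.

A disease's relevance at interval t aggregates its two copies: the event is
counted if it holds for either the interval-t node or the interval-(t-1) node
with respect to the interval-t target.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cohort_io import IntervalPanel

TARGET_NODE = "TARGET"


class RelevanceError(ValueError):
    pass


@dataclass
class RelevanceTable:
    """Disease-by-interval posterior strong-relevance probabilities.

    ``scores`` is a DataFrame indexed by disease code with one column per
    cumulative-interval end; ``provenance`` names the cohort (or
    "cross-cohort" for aggregated tables).
    """

    scores: pd.DataFrame
    provenance: str = "cohort"

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise RelevanceError("relevance scores must lie in [0, 1]")

    @classmethod
    def constant(
        cls,
        codes: list[str],
        interval_ends: tuple[float, ...],
        value: float = 1.0,
        provenance: str = "planted",
    ) -> "RelevanceTable":
        frame = pd.DataFrame(value, index=list(codes), columns=list(interval_ends))
        return cls(scores=frame, provenance=provenance)

    def to_tsv(self, path) -> None:
        long = self.scores.rename_axis("disease").reset_index().melt(
            id_vars="disease", var_name="interval_end", value_name="posterior"
        )
        long["cohort"] = self.provenance
        long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BDeu scoring
# ---------------------------------------------------------------------------


class _ScoreCache:
    """Decomposable BDeu family scores over a fixed discrete data matrix,
    memoized by (child, parent-set)."""

    def __init__(self, columns: list[np.ndarray], arities: list[int], ess: float):
        if ess <= 0:
            raise RelevanceError("ess must be positive")
        self.columns = columns
        self.arities = arities
        self.ess = float(ess)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family(self, child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = self.arities[child]
        q = 1
        code = None
        for p in sorted(parents):
            ap = self.arities[p]
            code = self.columns[p].astype(np.int64) if code is None else code * ap + self.columns[p]
            q *= ap
        if code is None:
            joint = np.bincount(self.columns[child], minlength=r).astype(float)
            joint = joint[None, :]
        else:
            joint = np.bincount(code * r + self.columns[child], minlength=q * r)
            joint = joint.reshape(q, r).astype(float)
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        n_j = joint.sum(axis=1)
        score = float(
            np.sum(gammaln(a_j) - gammaln(a_j + n_j))
            + np.sum(gammaln(a_jk + joint) - gammaln(a_jk))
        )
        self._cache[key] = score
        return score


@dataclass
class DagStructure:
    """A DAG over named nodes: parent sets per node, with prev-slice nodes
    (``parent_only``) forbidden from having parents of their own."""

    nodes: list[str]
    parents: dict[str, frozenset[str]]
    parent_only: frozenset[str] = frozenset()
    max_parents: int = 8

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        self.parents = {v: frozenset(self.parents.get(v, frozenset())) for v in self.nodes}
        for v, ps in self.parents.items():
            if not ps <= node_set:
                raise RelevanceError(f"unknown parents for {v!r}")
            if len(ps) > self.max_parents:
                raise RelevanceError(f"{v!r} exceeds max_parents={self.max_parents}")
            if v in self.parent_only and ps:
                raise RelevanceError(f"prev-slice node {v!r} may not have parents")
        # Kahn's algorithm for acyclicity
        indeg = {v: len(self.parents[v]) for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for v, ps in self.parents.items():
            for u in ps:
                children[u].append(v)
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for w in children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != len(self.nodes):
            raise RelevanceError("graph contains a cycle")


def score_structure(graph: DagStructure, data: pd.DataFrame, ess: float = 1.0) -> float:
    """Log marginal likelihood of ``graph`` given discrete ``data`` (BDeu).

    Complete cases only; decomposes as a sum of per-node family scores, so
    changing one parent set changes exactly one term.  With zero data rows
    every structure scores 0 (the empty product).
    """
    rows = data[graph.nodes].dropna()
    columns, arities = [], []
    index = {v: i for i, v in enumerate(graph.nodes)}
    for v in graph.nodes:
        col = rows[v].to_numpy()
        col = col.astype(np.int64)
        arity = max(2, int(col.max()) + 1) if len(col) else 2
        if len(col) and col.min() < 0:
            raise RelevanceError("data values must be nonnegative integer codes")
        columns.append(col)
        arities.append(arity)
    cache = _ScoreCache(columns, arities, ess)
    return sum(
        cache.family(index[v], frozenset(index[u] for u in graph.parents[v]))
        for v in graph.nodes
    )


# ---------------------------------------------------------------------------
# Panel -> node data assembly
# ---------------------------------------------------------------------------


@dataclass
class _Dataset:
    columns: list[np.ndarray]
    arities: list[int]
    names: list[str]
    is_current: np.ndarray  # bool per node
    target: int  # index of the current-slice target node
    candidates: list[str]  # disease codes / covariate names, target excluded
    groups: dict[str, list[int]]  # candidate -> node indices (its slice copies)


def _build_dataset(
    panel: IntervalPanel,
    target_codes: list[str] | str,
    interval: int,
    covariates: pd.DataFrame | None = None,
) -> _Dataset:
    if isinstance(target_codes, str):
        target_codes = [target_codes]
    for c in target_codes:
        if c not in panel.codes:
            raise RelevanceError(f"target code {c!r} not in panel")
    if not 0 <= interval < panel.grid.n_intervals:
        raise RelevanceError(f"interval {interval} out of range")
    rows = panel.included[:, interval]
    ind = panel.indicators[rows]
    tgt_idx = [panel.code_index(c) for c in target_codes]
    other = [c for c in panel.codes if c not in target_codes]

    names: list[str] = []
    columns: list[np.ndarray] = []
    arities: list[int] = []
    is_current: list[bool] = []
    groups: dict[str, list[int]] = {}

    def add(name: str, col: np.ndarray, current: bool, arity: int = 2) -> int:
        names.append(name)
        columns.append(col.astype(np.int64))
        arities.append(arity)
        is_current.append(current)
        return len(names) - 1

    target_col = (ind[:, tgt_idx, interval].max(axis=1) if tgt_idx else None)
    target = add(f"{TARGET_NODE}@t", target_col, True)
    slices = [(interval, "t", True)]
    if interval > 0:
        slices.append((interval - 1, "t-1", False))
        add(
            f"{TARGET_NODE}@t-1",
            ind[:, tgt_idx, interval - 1].max(axis=1),
            False,
        )
    dropped: list[str] = []
    for code in other:
        d = panel.code_index(code)
        idxs = []
        for t_idx, tag, current in slices:
            col = ind[:, d, t_idx]
            if len(col) and col.min() == col.max():
                dropped.append(f"{code}@{tag}")
                continue
            idxs.append(add(f"{code}@{tag}", col, current))
        if idxs:
            groups[code] = idxs
    if covariates is not None:
        cov = covariates.loc[rows] if len(covariates) == len(rows) else covariates
        for name in cov.columns:
            codes, _ = pd.factorize(cov[name].to_numpy(), sort=True)
            if len(codes) and codes.min() == codes.max():
                dropped.append(name)
                continue
            arity = max(2, int(codes.max()) + 1)
            groups[name] = [add(f"{name}@t", codes.astype(np.int64), True, arity)]
    if dropped:
        warnings.warn(
            f"excluding constant variables from candidate set: {dropped[:8]}",
            stacklevel=3,
        )
    return _Dataset(
        columns=columns,
        arities=arities,
        names=names,
        is_current=np.array(is_current),
        target=target,
        candidates=sorted(groups),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# MC^3 structure sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; the defaults mirror a full production run (2e6 burn-in,
    1e7 collected structures, parent limit 8) and should be reduced for
    exploratory work."""

    burn_in: int = 2_000_000
    n_samples: int = 10_000_000
    max_parents: int = 8
    n_chains: int = 4
    temperature_ratio: float = 1.5
    temperature_ladder: tuple[float, ...] | None = None
    ess: float = 1.0
    thin: int = 10
    swap_interval: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_samples < 1:
            raise RelevanceError("burn_in >= 0 and n_samples >= 1 required")
        if self.thin < 1 or self.n_chains < 1:
            raise RelevanceError("thin >= 1 and n_chains >= 1 required")
        ladder = self.temperature_ladder
        if ladder is None:
            ladder = tuple(self.temperature_ratio**i for i in range(self.n_chains))
        ladder = tuple(float(t) for t in ladder)
        if 1.0 not in ladder:
            raise RelevanceError("temperature ladder must include 1.0")
        object.__setattr__(self, "temperature_ladder", ladder)
        object.__setattr__(self, "n_chains", len(ladder))


@dataclass
class StructureTrace:
    """Thinned cold-chain record of the per-candidate strong-relevance
    indicator, plus chain diagnostics."""

    indicators: np.ndarray  # (n_kept, n_candidates) uint8
    candidates: list[str]
    log_scores: np.ndarray  # cold-chain score at each kept sample
    acceptance_rate: float
    swap_rate: float
    settings: McmcSettings


class _ChainState:
    __slots__ = ("parents", "children", "scores", "total", "desc")

    def __init__(self, n_nodes: int, cache: _ScoreCache):
        self.parents = [set() for _ in range(n_nodes)]
        self.children = [set() for _ in range(n_nodes)]
        self.scores = [cache.family(v, frozenset()) for v in range(n_nodes)]
        self.total = float(sum(self.scores))
        self.desc: list[set[int]] = [set() for _ in range(n_nodes)]

    def recompute_desc(self) -> None:
        # descendant sets; only current-slice nodes can lie on a cycle, but
        # computing over all nodes is cheap at these sizes
        for v in range(len(self.parents)):
            seen: set[int] = set()
            stack = list(self.children[v])
            while stack:
                w = stack.pop()
                if w not in seen:
                    seen.add(w)
                    stack.extend(self.children[w])
            self.desc[v] = seen


def mcmc_sample(
    panel: IntervalPanel,
    target_codes: list[str] | str,
    interval: int,
    covariates: pd.DataFrame | None = None,
    settings: McmcSettings | None = None,
) -> StructureTrace:
    """Run MC^3 structure MCMC on the interval-t slice of the panel and record
    the strong-relevance indicator of every candidate variable.

    Only participants observed through the interval end enter the data.
    Moves are add/delete/reverse-edge proposals drawn uniformly from a fixed
    move enumeration (invalid draws are rejected in place, keeping the kernel
    symmetric); tempered chains attempt adjacent-state swaps every
    ``swap_interval`` steps.  Deterministic given ``settings.seed``.
    """
    settings = settings or McmcSettings()
    ds = _build_dataset(panel, target_codes, interval, covariates)
    cache = _ScoreCache(ds.columns, ds.arities, settings.ess)
    rng = np.random.default_rng(settings.seed)
    n_nodes = len(ds.names)
    max_parents = settings.max_parents

    n_kept = settings.n_samples // settings.thin
    if not ds.candidates:
        return StructureTrace(
            indicators=np.zeros((n_kept, 0), dtype=np.uint8),
            candidates=[],
            log_scores=np.zeros(n_kept),
            acceptance_rate=0.0,
            swap_rate=0.0,
            settings=settings,
        )

    current_nodes = np.flatnonzero(ds.is_current)
    pairs = [
        (u, v) for v in current_nodes for u in range(n_nodes) if u != v
    ]
    n_pairs = len(pairs)
    temps = settings.temperature_ladder
    chains = [_ChainState(n_nodes, cache) for _ in temps]
    cold = temps.index(1.0)

    groups = [ds.groups[c] for c in ds.candidates]
    target = ds.target
    indicators = np.zeros((n_kept, len(groups)), dtype=np.uint8)
    log_scores = np.zeros(n_kept)
    kept = 0
    accepted = 0
    proposed = 0
    swaps_acc = 0
    swaps_try = 0

    total_steps = settings.burn_in + settings.n_samples
    block = 8192
    for start in range(0, total_steps, block):
        steps = min(block, total_steps - start)
        moves = rng.integers(0, 3 * n_pairs, size=(steps, len(temps)))
        unifs = rng.random(size=(steps, len(temps)))
        swap_unifs = rng.random(size=steps)
        swap_picks = rng.integers(0, max(1, len(temps) - 1), size=steps)
        for s in range(steps):
            step = start + s
            for ci, chain in enumerate(chains):
                m = moves[s, ci]
                action, pair = divmod(m, n_pairs)
                u, v = pairs[pair]
                proposed += 1
                parents_v = chain.parents[v]
                if action == 0:  # add u -> v
                    if (
                        u in parents_v
                        or v in chain.parents[u]
                        or len(parents_v) >= max_parents
                        or u in chain.desc[v]
                    ):
                        continue
                    new = cache.family(v, frozenset(parents_v | {u}))
                    delta = new - chain.scores[v]
                    if delta >= 0 or unifs[s, ci] < np.exp(delta / temps[ci]):
                        parents_v.add(u)
                        chain.children[u].add(v)
                        chain.total += new - chain.scores[v]
                        chain.scores[v] = new
                        chain.recompute_desc()
                        accepted += 1
                elif action == 1:  # delete u -> v
                    if u not in parents_v:
                        continue
                    new = cache.family(v, frozenset(parents_v - {u}))
                    delta = new - chain.scores[v]
                    if delta >= 0 or unifs[s, ci] < np.exp(delta / temps[ci]):
                        parents_v.remove(u)
                        chain.children[u].discard(v)
                        chain.total += new - chain.scores[v]
                        chain.scores[v] = new
                        chain.recompute_desc()
                        accepted += 1
                else:  # reverse u -> v
                    if u not in parents_v or not ds.is_current[u]:
                        continue
                    if len(chain.parents[u]) >= max_parents:
                        continue
                    if any(
                        w != v and v in chain.desc[w] for w in chain.children[u]
                    ):
                        continue
                    new_v = cache.family(v, frozenset(parents_v - {u}))
                    new_u = cache.family(u, frozenset(chain.parents[u] | {v}))
                    delta = (new_v - chain.scores[v]) + (new_u - chain.scores[u])
                    if delta >= 0 or unifs[s, ci] < np.exp(delta / temps[ci]):
                        parents_v.remove(u)
                        chain.children[u].discard(v)
                        chain.parents[u].add(v)
                        chain.children[v].add(u)
                        chain.total += delta
                        chain.scores[v] = new_v
                        chain.scores[u] = new_u
                        chain.recompute_desc()
                        accepted += 1
            if len(temps) > 1 and (step + 1) % settings.swap_interval == 0:
                i = int(swap_picks[s])
                j = i + 1
                swaps_try += 1
                log_r = (1.0 / temps[i] - 1.0 / temps[j]) * (
                    chains[j].total - chains[i].total
                )
                if log_r >= 0 or swap_unifs[s] < np.exp(log_r):
                    chains[i], chains[j] = chains[j], chains[i]
                    swaps_acc += 1
            if step >= settings.burn_in and (step - settings.burn_in) % settings.thin == 0:
                if kept < n_kept:
                    c = chains[cold]
                    tp = c.parents[target]
                    tc = c.children[target]
                    for gi, nodes in enumerate(groups):
                        rel = 0
                        for x in nodes:
                            if (
                                x in tp
                                or target in c.parents[x]
                                or (c.children[x] & tc)
                            ):
                                rel = 1
                                break
                        indicators[kept, gi] = rel
                    log_scores[kept] = c.total
                    kept += 1
    return StructureTrace(
        indicators=indicators[:kept],
        candidates=ds.candidates,
        log_scores=log_scores[:kept],
        acceptance_rate=accepted / max(1, proposed),
        swap_rate=swaps_acc / max(1, swaps_try),
        settings=settings,
    )


def strong_relevance_posterior(trace: StructureTrace) -> pd.Series:
    """Posterior strong-relevance probability per candidate: the mean of the
    cold-chain indicator over the recorded samples."""
    if trace.indicators.shape[0] == 0:
        raise RelevanceError("empty trace")
    return pd.Series(
        trace.indicators.mean(axis=0), index=trace.candidates, name="relevance"
    )


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------


def exact_relevance_posterior(
    panel: IntervalPanel,
    target_codes: list[str] | str,
    interval: int,
    covariates: pd.DataFrame | None = None,
    ess: float = 1.0,
    max_parents: int = 8,
    limit: int = 5,
) -> pd.Series:
    """Exact strong-relevance posteriors by enumeration over all constraint-
    respecting DAGs, under the same BDeu score and uniform structure prior as
    the sampler.

    Prev-slice parent subsets are marginalized analytically within each node
    family (they cannot create cycles), so only the within-slice DAGs are
    enumerated explicitly; feasible for at most ``limit`` current-slice nodes.
    """
    ds = _build_dataset(panel, target_codes, interval, covariates)
    cache = _ScoreCache(ds.columns, ds.arities, ess)
    current = [i for i in range(len(ds.names)) if ds.is_current[i]]
    prev = [i for i in range(len(ds.names)) if not ds.is_current[i]]
    if len(current) > limit:
        raise RelevanceError(
            f"exact enumeration limited to {limit} current-slice variables "
            f"(got {len(current)}); use mcmc_sample instead"
        )

    # family marginals over prev-parent subsets, per (node, within-slice set)
    log_w: dict[tuple[int, frozenset[int]], float] = {}
    log_wu: dict[tuple[int, frozenset[int]], dict[int, float]] = {}
    for v in current:
        others = [c for c in current if c != v]
        for r in range(min(len(others), max_parents) + 1):
            for s_tuple in itertools.combinations(others, r):
                s = frozenset(s_tuple)
                terms = []
                per_u: dict[int, list[float]] = {u: [] for u in prev}
                room = max_parents - len(s)
                for pr in range(min(len(prev), room) + 1):
                    for p_tuple in itertools.combinations(prev, pr):
                        f = cache.family(v, s | frozenset(p_tuple))
                        terms.append(f)
                        for u in p_tuple:
                            per_u[u].append(f)
                log_w[(v, s)] = float(logsumexp(terms))
                log_wu[(v, s)] = {
                    u: (float(logsumexp(per_u[u])) if per_u[u] else -np.inf)
                    for u in prev
                }

    target = ds.target
    cand_names = ds.candidates
    groups = [ds.groups[c] for c in cand_names]
    cand_cur = []
    cand_prev = []
    for nodes in groups:
        cur = [x for x in nodes if ds.is_current[x]]
        prv = [x for x in nodes if not ds.is_current[x]]
        cand_cur.append(cur[0] if cur else None)
        cand_prev.append(prv[0] if prv else None)

    pairs = list(itertools.combinations(current, 2))
    log_weights: list[float] = []
    rel_probs: list[np.ndarray] = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        parent_sets: dict[int, set[int]] = {v: set() for v in current}
        for (a, b), st in zip(pairs, states):
            if st == 1:
                parent_sets[b].add(a)
            elif st == 2:
                parent_sets[a].add(b)
        if any(len(s) > max_parents for s in parent_sets.values()):
            continue
        if not _acyclic(current, parent_sets):
            continue
        lw = 0.0
        for v in current:
            lw += log_w[(v, frozenset(parent_sets[v]))]
        children_of_target = [v for v in current if target in parent_sets[v]]
        probs = np.zeros(len(groups))
        for gi in range(len(groups)):
            xc, xp = cand_cur[gi], cand_prev[gi]
            a1 = False
            if xc is not None:
                a1 = (
                    xc in parent_sets[target]
                    or target in parent_sets[xc]
                    or any(
                        xc in parent_sets[z] and target in parent_sets[z]
                        for z in current
                    )
                )
            if a1:
                probs[gi] = 1.0
                continue
            p_not = 1.0
            if xp is not None:
                s_y = frozenset(parent_sets[target])
                p2 = np.exp(log_wu[(target, s_y)][xp] - log_w[(target, s_y)])
                p_not *= 1.0 - p2
                for z in children_of_target:
                    s_z = frozenset(parent_sets[z])
                    p3 = np.exp(log_wu[(z, s_z)][xp] - log_w[(z, s_z)])
                    p_not *= 1.0 - p3
            probs[gi] = 1.0 - p_not
        log_weights.append(lw)
        rel_probs.append(probs)
    log_weights_arr = np.asarray(log_weights)
    weights = np.exp(log_weights_arr - logsumexp(log_weights_arr))
    posterior = np.clip(weights @ np.vstack(rel_probs), 0.0, 1.0)
    return pd.Series(posterior, index=cand_names, name="relevance")


def _acyclic(nodes: list[int], parent_sets: dict[int, set[int]]) -> bool:
    indeg = {v: len(parent_sets[v]) for v in nodes}
    children: dict[int, list[int]] = {v: [] for v in nodes}
    for v in nodes:
        for u in parent_sets[v]:
            children[u].append(v)
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for w in children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def geweke_diagnostic(
    trace: StructureTrace | np.ndarray,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
) -> pd.Series:
    """Geweke convergence z-scores on the relevance-indicator trace.

    Compares the mean of the first ``first_frac`` of the trace with the mean
    of the last ``last_frac``, with autocorrelation-robust (Bartlett-window
    spectral) variance estimates; |z| <= 2 is the conventional convergence
    window.  A constant trace yields z = 0.
    """
    if isinstance(trace, StructureTrace):
        data = trace.indicators.astype(float)
        names = trace.candidates
    else:
        data = np.atleast_2d(np.asarray(trace, dtype=float).T).T
        names = list(range(data.shape[1]))
    n = data.shape[0]
    if n < 100:
        raise RelevanceError("trace length must be >= 100 for Geweke diagnostics")
    n_first = max(2, int(first_frac * n))
    n_last = max(2, int(last_frac * n))
    zs = []
    for j in range(data.shape[1]):
        x = data[:, j]
        a, b = x[:n_first], x[-n_last:]
        va = _spectral_variance_of_mean(a)
        vb = _spectral_variance_of_mean(b)
        denom = np.sqrt(va + vb)
        gap = a.mean() - b.mean()
        if denom == 0:
            # both segments constant: converged iff they agree
            zs.append(0.0 if gap == 0 else float(np.sign(gap) * np.inf))
        else:
            zs.append(float(gap / denom))
    return pd.Series(zs, index=names, name="geweke_z")


def _spectral_variance_of_mean(x: np.ndarray) -> float:
    n = len(x)
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    if g0 == 0:
        return 0.0
    window = max(1, int(round(n ** (1.0 / 3.0))))
    s = g0
    for lag in range(1, min(window, n - 1) + 1):
        gamma = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (window + 1.0)) * gamma
    return max(s, 0.0) / n
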