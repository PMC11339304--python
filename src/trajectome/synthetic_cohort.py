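"""Synthetic cohorts, gene-score tables and interactomes with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes rather than any particular biobank: a small number of latent
trajectory clusters, piecewise-constant age-band onset hazards with
per-cluster multipliers, a designated target disease (the depression
analogue) whose hazard is boosted once any *direct parent* disease has
onset, *mediated* diseases that influence the target exclusively through a
named mediator disease, heterogeneous right-censoring ages, and basic
covariates (sex, birth year, household income).

Risk multipliers triggered by parent onsets take effect at the next age-band
boundary.  Because the downstream dynamic-Bayesian-network analysis only ever
sees band-level cumulative indicators, this convention makes mediated
diseases *exactly* conditionally independent of the target given the mediator
at the panel level, so the planted direct/mediated distinction is recoverable
in principle, not just approximately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import CohortTable, TimeGrid


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class DiseaseSpec:
    """One disease: code, baseline hazard per age band, per-cluster multipliers.

    ``baseline_hazard`` has one rate (events/year) per band of the TimeGrid;
    the final band's rate also applies beyond the last interval end.
    ``cluster_multipliers`` has one nonnegative factor per latent cluster.
    """

    code: str
    baseline_hazard: tuple[float, ...]
    cluster_multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "baseline_hazard", tuple(float(h) for h in self.baseline_hazard)
        )
        object.__setattr__(
            self,
            "cluster_multipliers",
            tuple(float(m) for m in self.cluster_multipliers),
        )
        if any(h < 0 for h in self.baseline_hazard) or any(
            m < 0 for m in self.cluster_multipliers
        ):
            raise SyntheticConfigError(f"negative hazard for disease {self.code!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int
    diseases: tuple[DiseaseSpec, ...]
    target_code: str
    n_clusters: int = 7
    direct_parents: tuple[str, ...] = ()
    mediated_diseases: tuple[str, ...] = ()
    mediator: str | None = None
    parent_effect: float = 1.0  # log-HR on target once any direct parent has onset
    mediated_effect: float = 1.0  # log-HR on mediator once any mediated disease has onset
    censor_age_range: tuple[float, float] = (55.0, 80.0)
    cluster_mixture: tuple[float, ...] | None = None
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    birth_year_range: tuple[int, int] = (1940, 1970)
    grid: TimeGrid = field(default_factory=TimeGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0 or self.n_clusters < 1:
            raise SyntheticConfigError("n_participants >= 0 and n_clusters >= 1 required")
        mixture = self.cluster_mixture
        if mixture is None:
            mixture = tuple([1.0 / self.n_clusters] * self.n_clusters)
        mixture = tuple(float(p) for p in mixture)
        if len(mixture) != self.n_clusters:
            raise SyntheticConfigError("cluster_mixture length != n_clusters")
        if any(p < 0 for p in mixture) or abs(sum(mixture) - 1.0) > 1e-12:
            raise SyntheticConfigError("cluster_mixture must be a probability vector")
        object.__setattr__(self, "cluster_mixture", mixture)
        codes = [d.code for d in self.diseases]
        if len(set(codes)) != len(codes):
            raise SyntheticConfigError("duplicate disease codes")
        if self.target_code not in codes:
            raise SyntheticConfigError("target_code must be among the diseases")
        if set(self.direct_parents) & set(self.mediated_diseases):
            raise SyntheticConfigError(
                "direct_parents and mediated_diseases must be disjoint"
            )
        if self.mediated_diseases and self.mediator is None:
            raise SyntheticConfigError("mediated diseases require a mediator code")
        if self.mediator is not None and self.mediator not in self.direct_parents:
            raise SyntheticConfigError("mediator must be a direct parent of the target")
        for group in (self.direct_parents, self.mediated_diseases):
            unknown = set(group) - set(codes)
            if unknown:
                raise SyntheticConfigError(f"unknown disease codes {sorted(unknown)}")
        n_bands = self.grid.n_intervals
        for d in self.diseases:
            if len(d.baseline_hazard) != n_bands:
                raise SyntheticConfigError(
                    f"disease {d.code!r}: need one baseline hazard per age band"
                )
            if len(d.cluster_multipliers) != self.n_clusters:
                raise SyntheticConfigError(
                    f"disease {d.code!r}: need one multiplier per cluster"
                )
        lo, hi = self.censor_age_range
        if not 0 < lo <= hi:
            raise SyntheticConfigError("invalid censor_age_range")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort: cluster labels (1-based), the
    direct/mediated/irrelevant flag per disease, and the planted per-cluster
    hazard multipliers."""

    labels: np.ndarray  # (n_participants,), values in 1..n_clusters
    disease_flags: dict[str, str]  # code -> direct | mediated | irrelevant | target
    hazard_multipliers: dict[str, tuple[float, ...]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.tolist(),
            "disease_flags": self.disease_flags,
            "hazard_multipliers": {
                k: list(v) for k, v in self.hazard_multipliers.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def _sample_piecewise_onsets(
    rates: np.ndarray, band_edges: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """First-event times under piecewise-constant hazards, by inversion.

    ``rates`` is (n_participants, n_bands); the last band extends to +inf.
    Returns onset ages (inf when no event ever occurs).
    """
    n, n_bands = rates.shape
    widths = np.diff(band_edges)  # one width per finite band
    # cumulative hazard at the band edges; the last band's rate continues to +inf
    cum = np.cumsum(rates * widths[None, :], axis=1)
    cum = np.concatenate([np.zeros((n, 1)), cum], axis=1)  # (n, n_bands + 1)
    e = rng.exponential(size=n)
    onset = np.full(n, np.inf)
    remaining = np.ones(n, dtype=bool)
    for b in range(n_bands + 1):
        rate = rates[:, min(b, n_bands - 1)]
        lo = cum[:, b]
        hi = cum[:, b + 1] if b < n_bands else np.full(n, np.inf)
        start = band_edges[min(b, n_bands)]
        hit = remaining & (e < hi) & (rate > 0) & (e >= lo)
        onset[hit] = start + (e[hit] - lo[hit]) / rate[hit]
        remaining &= ~hit
    return onset


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, TruthRecord]:
    """Draw a cohort from the planted trajectory-cluster model.

    Deterministic given ``config.seed``.  Onsets after the participant's
    censoring age are discarded (they never influenced any recorded onset,
    because parent effects switch on only at band boundaries).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    grid = config.grid
    band_edges = np.asarray(grid.band_edges)
    n_bands = grid.n_intervals

    labels0 = rng.choice(config.n_clusters, size=n, p=np.asarray(config.cluster_mixture))
    sex = rng.integers(0, 2, size=n)
    income = rng.integers(0, 3, size=n)
    birth_year = rng.integers(
        config.birth_year_range[0], config.birth_year_range[1] + 1, size=n
    )
    lo, hi = config.censor_age_range
    censor_age = rng.uniform(lo, hi, size=n)

    specs = {d.code: d for d in config.diseases}
    target = config.target_code
    mediator = config.mediator
    plain = [
        d.code
        for d in config.diseases
        if d.code != target and d.code != mediator
    ]

    onset_ages: dict[str, np.ndarray] = {}

    def base_rates(code: str) -> np.ndarray:
        spec = specs[code]
        mult = np.asarray(spec.cluster_multipliers)[labels0]
        return np.asarray(spec.baseline_hazard)[None, :] * mult[:, None]

    for code in plain:
        onset_ages[code] = _sample_piecewise_onsets(base_rates(code), band_edges, rng)

    def group_onset_by_band_start(codes: Sequence[str]) -> np.ndarray:
        """(n, n_bands) indicator: any onset among ``codes`` at or before the
        band's start (effects engage at band boundaries)."""
        ind = np.zeros((n, n_bands), dtype=bool)
        for code in codes:
            ages = onset_ages[code]
            ind |= ages[:, None] <= band_edges[None, :-1]
        return ind

    if mediator is not None:
        rates = base_rates(mediator)
        boost = group_onset_by_band_start(list(config.mediated_diseases))
        rates = rates * np.exp(config.mediated_effect * boost)
        onset_ages[mediator] = _sample_piecewise_onsets(rates, band_edges, rng)

    rates = base_rates(target)
    if config.direct_parents:
        boost = group_onset_by_band_start(list(config.direct_parents))
        rates = rates * np.exp(config.parent_effect * boost)
    cov_lp = np.zeros(n)
    cov_values = {"sex": sex, "income": income}
    for name, coef in config.covariate_effects.items():
        if name not in cov_values:
            raise SyntheticConfigError(f"unknown covariate {name!r}")
        cov_lp += coef * cov_values[name]
    rates = rates * np.exp(cov_lp)[:, None]
    onset_ages[target] = _sample_piecewise_onsets(rates, band_edges, rng)

    ids = np.array([f"P{i:06d}" for i in range(n)])
    records = []
    for code in sorted(onset_ages):
        ages = onset_ages[code]
        keep = ages <= censor_age
        if keep.any():
            records.append(
                pd.DataFrame(
                    {
                        "participant_id": ids[keep],
                        "disease_code": code,
                        "onset_age": ages[keep],
                    }
                )
            )
    onsets = (
        pd.concat(records, ignore_index=True)
        .sort_values(["participant_id", "disease_code"], kind="stable")
        .reset_index(drop=True)
        if records
        else pd.DataFrame(
            {"participant_id": ids[:0], "disease_code": [], "onset_age": []}
        )
    )
    covariates = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "birth_year": birth_year,
            "income": income,
            "censor_age": censor_age,
        }
    )
    cohort = CohortTable(onsets=onsets, covariates=covariates)

    flags = {}
    for d in config.diseases:
        if d.code == target:
            flags[d.code] = "target"
        elif d.code in config.direct_parents:
            flags[d.code] = "direct"
        elif d.code in config.mediated_diseases:
            flags[d.code] = "mediated"
        else:
            flags[d.code] = "irrelevant"
    truth = TruthRecord(
        labels=labels0 + 1,
        disease_flags=flags,
        hazard_multipliers={d.code: d.cluster_multipliers for d in config.diseases},
    )
    return cohort, truth


def well_separated_trajectory_config(
    n_participants: int = 10_000,
    seed: int = 0,
    n_clusters: int = 7,
    markers_per_group: int = 8,
    band_onset_prob: float = 0.97,
    background_multiplier: float = 0.01,
) -> SyntheticConfig:
    """Canonical 7-cluster study configuration with well-separated score
    trajectories.

    Marker diseases come in five groups, each with its onset hazard
    concentrated in a single age band; clusters switch different group
    combinations on, so their expected cumulative multimorbidity-score
    vectors sit at least six within-cluster standard deviations apart in the
    4-dimensional score space (the separation regime assumed by the
    planted-cluster recovery checks).
    """
    if n_clusters != 7:
        raise SyntheticConfigError("the canonical trajectory config plants 7 clusters")
    grid = TimeGrid()
    edges = np.asarray(grid.band_edges)
    widths = np.diff(edges)
    n_bands = grid.n_intervals
    # group g (0..3) onsets in band g; group 4 is a second band-3 group
    group_bands = [0, 1, 2, 3, 3]
    # cluster -> active marker groups, chosen so cumulative count profiles
    # are pairwise >= one full group apart
    activation = [
        (),
        (3,),
        (2, 3),
        (1, 2, 3),
        (0, 1, 2, 3),
        (1, 2, 3, 4),
        (0, 1, 2, 3, 4),
    ]
    diseases = []
    for g, band in enumerate(group_bands):
        rate = -np.log(1.0 - band_onset_prob) / widths[band]
        hazard = tuple(rate if b == band else 0.0 for b in range(n_bands))
        for m in range(markers_per_group):
            mult = tuple(
                1.0 if g in activation[c] else background_multiplier
                for c in range(n_clusters)
            )
            diseases.append(DiseaseSpec(f"K{g}{m}", hazard, mult))
    diseases.append(DiseaseSpec("F32", (0.003,) * n_bands, (1.0,) * n_clusters))
    return SyntheticConfig(
        n_participants=n_participants,
        n_clusters=n_clusters,
        diseases=tuple(diseases),
        target_code="F32",
        censor_age_range=(50.0, 85.0),
        grid=grid,
        seed=seed,
    )


def markov_boundary_config(
    n_participants: int = 20_000,
    seed: int = 0,
    parent_effect: float = 1.5,
    mediated_effect: float = 1.5,
) -> SyntheticConfig:
    """Canonical configuration for the direct-versus-mediated distinction.

    A single latent cluster (so no unobserved confounder links the diseases),
    two direct parents of the target (one of them the mediator), two
    mediated diseases acting only on the mediator, and one irrelevant
    disease.  Prevalences are in the tens of percent by age 70 so the
    interval indicators carry signal.
    """
    h = (0.008,) * 4
    return SyntheticConfig(
        n_participants=n_participants,
        n_clusters=1,
        diseases=(
            DiseaseSpec("D01", h, (1.0,)),
            DiseaseSpec("D02", h, (1.0,)),
            DiseaseSpec("M01", h, (1.0,)),
            DiseaseSpec("M02", h, (1.0,)),
            DiseaseSpec("R01", h, (1.0,)),
            DiseaseSpec("F32", (0.004,) * 4, (1.0,)),
        ),
        target_code="F32",
        direct_parents=("D01", "D02"),
        mediator="D01",
        mediated_diseases=("M01", "M02"),
        parent_effect=parent_effect,
        mediated_effect=mediated_effect,
        censor_age_range=(60.0, 80.0),
        seed=seed,
    )


def generate_gene_scores(
    n_genes: int,
    signal_genes: Sequence[str] = (),
    effect: float = 1.0,
    seed: int = 0,
    p_floor: float = 1e-8,
) -> pd.DataFrame:
    """Gene-level adjusted p-values with optional planted signal genes.

    Background genes draw p ~ Uniform(0, 1]; signal genes draw
    ``p_floor + (1 - p_floor) * U**exp(effect)``, which is stochastically
    smaller and tends to ``p_floor`` as ``effect`` grows.  Returns a DataFrame
    with columns gene_id, p_adj.
    """
    if effect <= 0:
        raise SyntheticConfigError("effect must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    unknown = set(signal_genes) - set(genes)
    if unknown:
        raise SyntheticConfigError(f"signal genes outside universe: {sorted(unknown)[:5]}")
    u = rng.uniform(size=n_genes)
    p = 1.0 - u  # Uniform(0, 1]
    signal = np.isin(genes, list(signal_genes))
    p[signal] = p_floor + (1.0 - p_floor) * rng.uniform(size=signal.sum()) ** np.exp(
        effect
    )
    return pd.DataFrame({"gene_id": genes, "p_adj": p})


def generate_interactome(
    n_nodes: int,
    n_modules: int,
    intra_p: float,
    inter_p: float,
    seed: int = 0,
) -> nx.Graph:
    """Planted-partition interactome: ``n_modules`` near-equal blocks with
    within-block edge probability ``intra_p`` and between-block ``inter_p``.

    Node names are gene identifiers; each node carries a ``module`` attribute
    with its planted block, and the graph carries ``largest_component_size``.
    """
    if n_modules > n_nodes:
        raise SyntheticConfigError("n_modules may not exceed n_nodes")
    if not (0 <= inter_p < intra_p <= 1):
        raise SyntheticConfigError("require 0 <= inter_p < intra_p <= 1")
    sizes = [n_nodes // n_modules] * n_modules
    for i in range(n_nodes - sum(sizes)):
        sizes[i] += 1
    sbm = nx.stochastic_block_model(
        sizes, _block_matrix(n_modules, intra_p, inter_p), seed=int(seed)
    )
    graph = nx.Graph()
    names = [f"G{i:05d}" for i in range(n_nodes)]
    blocks = []
    for b, size in enumerate(sizes):
        blocks.extend([b] * size)
    for i, name in enumerate(names):
        graph.add_node(name, module=blocks[i])
    for u, v in sbm.edges():
        if u != v:
            graph.add_edge(names[u], names[v])
    if graph.number_of_nodes():
        graph.graph["largest_component_size"] = max(
            (len(c) for c in nx.connected_components(graph)), default=0
        )
    return graph


def _block_matrix(k: int, intra_p: float, inter_p: float) -> list[list[float]]:
    return [[intra_p if i == j else inter_p for j in range(k)] for i in range(k)]


def write_gene_scores(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_interactome(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


def read_interactome(path: str | Path) -> nx.Graph:
    graph = nx.read_edgelist(path, delimiter="\t")
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph
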