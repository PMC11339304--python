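import numpy as np
import pandas as pd
import pytest

from trajectome import (
    RelevanceTable,
    assign,
    discretize,
    fit_clusters,
    generate_cohort,
    multimorbidity_scores,
)
from trajectome.synthetic_cohort import (
    markov_boundary_config,
    well_separated_trajectory_config,
)


@pytest.fixture(scope="session")
def trajectory_data():
    """Well-separated 7-cluster cohort with the full clustering pipeline run:
    panel, planted relevance, scores, fitted model and reference memberships."""
    cohort, truth = generate_cohort(well_separated_trajectory_config(6000, seed=11))
    panel = discretize(cohort)
    codes = [c for c in panel.codes if c != "F32"]
    marker_panel = panel.restrict(codes)
    relevance = RelevanceTable.constant(codes, panel.grid.interval_ends, 1.0)
    scores = multimorbidity_scores(marker_panel, relevance)
    model = fit_clusters(scores, k=7, seed=0)
    reference = assign(scores, model)
    return {
        "cohort": cohort,
        "truth": truth,
        "panel": marker_panel,
        "relevance": relevance,
        "scores": scores,
        "model": model,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def markov_panel():
    """Panel of the direct/mediated discrimination cohort (single seed)."""
    cohort, truth = generate_cohort(markov_boundary_config(20_000, seed=7))
    return discretize(cohort), truth


@pytest.fixture()
def tiny_cohort():
    """Four hand-built participants with known onsets, for direct evaluation."""
    from trajectome import CohortTable

    covariates = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c", "d"],
            "sex": [0, 1, 0, 1],
            "birth_year": [1950, 1955, 1960, 1945],
            "income": [0, 1, 2, 1],
            "censor_age": [70.0, 70.0, 70.0, 70.0],
        }
    )
    onsets = pd.DataFrame(
        {
            "participant_id": ["a", "b"],
            "disease_code": ["X40", "X40"],
            "onset_age": [50.0, 60.0],
        }
    )
    return CohortTable(onsets=onsets, covariates=covariates)
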