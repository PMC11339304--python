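import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trajectome import (
    ClusterModel,
    RelevanceTable,
    TimeGrid,
    assign,
    confidence_filter,
    cross_cohort_scores,
    federated_fit,
    fit_clusters,
    logodds_matrix,
    multimorbidity_scores,
    posterior_matrix,
    select_diseases,
)
from trajectome.cluster_engine import ClusterError

ENDS = (20.0, 40.0, 60.0, 70.0)


def _relevance(values: dict[str, list[float]], provenance="cohort"):
    return RelevanceTable(
        scores=pd.DataFrame(values, index=list(ENDS)).T, provenance=provenance
    )


def _model(centres, seed=0):
    centres = np.asarray(centres, dtype=float)
    return ClusterModel(
        k=len(centres),
        centres=centres,
        interval_ends=tuple(range(centres.shape[1])),
        inertia=1.0,
        silhouette=None,
        seed=seed,
    )


class TestCrossCohort:
    def test_uniform_weights_average_cells(self):
        a = _relevance({"D01": [0.4] * 4})
        b = _relevance({"D01": [0.8] * 4})
        out = cross_cohort_scores([a, b])
        assert out.scores.loc["D01"].tolist() == pytest.approx([0.6] * 4)
        assert out.provenance == "cross-cohort"

    def test_single_cohort_is_identity(self):
        a = _relevance({"D01": [0.4, 0.5, 0.6, 0.7]})
        out = cross_cohort_scores([a])
        pd.testing.assert_frame_equal(out.scores, a.scores)

    def test_disease_absent_from_one_cohort_excluded(self):
        a = _relevance({"D01": [0.4] * 4, "D02": [0.9] * 4})
        b = _relevance({"D01": [0.8] * 4})
        out = cross_cohort_scores([a, b])
        assert list(out.scores.index) == ["D01"]

    def test_select_diseases_strict_cutoff(self):
        a = _relevance({"D01": [0.5, 0.5, 0.5, 0.5], "D02": [0.51, 0.1, 0.1, 0.1]})
        assert select_diseases([a], 0.5) == ["D02"]

    def test_select_diseases_any_cohort_any_interval(self):
        a = _relevance({"D01": [0.1] * 4})
        b = _relevance({"D01": [0.1, 0.1, 0.51, 0.1]})
        assert select_diseases([a, b], 0.5) == ["D01"]


class TestScores:
    def _panel(self, onset_ages: dict[str, float], censor=75.0):
        from trajectome import CohortTable, discretize

        cov = pd.DataFrame(
            {
                "participant_id": ["a"],
                "sex": [0],
                "birth_year": [1950],
                "income": [1],
                "censor_age": [censor],
            }
        )
        onsets = pd.DataFrame(
            {
                "participant_id": ["a"] * len(onset_ages),
                "disease_code": list(onset_ages),
                "onset_age": list(onset_ages.values()),
            }
        )
        return discretize(CohortTable(onsets=onsets, covariates=cov))

    def test_no_onsets_gives_zero_scores(self):
        panel = self._panel({"D01": 10.0}).restrict(["D01"])
        panel.indicators[:] = 0
        rel = _relevance({"D01": [0.6] * 4})
        scores = multimorbidity_scores(panel, rel)
        assert scores.iloc[0].tolist() == [0.0] * 4

    def test_early_onset_counts_in_every_interval(self):
        panel = self._panel({"D01": 10.0})
        rel = _relevance({"D01": [0.6] * 4})
        scores = multimorbidity_scores(panel, rel)
        assert scores.iloc[0].tolist() == [0.6] * 4

    def test_two_onsets_weighted_sum(self):
        panel = self._panel({"D01": 30.0, "D02": 65.0})
        rel = _relevance({"D01": [0.2, 0.5, 0.5, 0.4], "D02": [0.1, 0.1, 0.1, 0.3]})
        scores = multimorbidity_scores(panel, rel)
        assert scores.iloc[0].tolist() == pytest.approx([0.0, 0.5, 0.5, 0.7])

    def test_missing_relevance_names_disease(self):
        panel = self._panel({"D01": 30.0, "D02": 65.0})
        rel = _relevance({"D01": [0.2] * 4})
        with pytest.raises(ClusterError, match="D02"):
            multimorbidity_scores(panel, rel)

    def test_unobserved_intervals_are_missing(self):
        panel = self._panel({"D01": 30.0}, censor=50.0)
        rel = _relevance({"D01": [0.2] * 4})
        scores = multimorbidity_scores(panel, rel)
        assert scores.iloc[0, :2].notna().all()
        assert scores.iloc[0, 2:].isna().all()


class TestFitClusters:
    def test_identical_rows_give_degenerate_model(self):
        scores = pd.DataFrame(np.ones((20, 4)), columns=ENDS)
        model = fit_clusters(scores, k=2, seed=0)
        assert model.degenerate
        assert np.allclose(model.centres, 1.0)
        assert model.inertia == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.random((200, 4)), columns=ENDS)
        m1 = fit_clusters(scores, k=3, seed=5)
        m2 = fit_clusters(scores, k=3, seed=5)
        assert np.array_equal(m1.centres, m2.centres)

    def test_too_few_complete_rows_rejected(self):
        scores = pd.DataFrame(np.ones((3, 4)), columns=ENDS)
        with pytest.raises(ClusterError):
            fit_clusters(scores, k=5)

    def test_planted_clusters_recovered(self, trajectory_data):
        from sklearn.metrics import adjusted_rand_score

        truth = pd.Series(
            trajectory_data["truth"].labels, index=trajectory_data["panel"].participants
        )
        complete = trajectory_data["scores"].dropna().index
        ari = adjusted_rand_score(
            truth.loc[complete],
            trajectory_data["reference"].loc[complete, "hard_label"],
        )
        assert ari >= 0.9


class TestAssign:
    def test_closed_form_two_cluster_posteriors(self):
        model = _model([[0.0, 0.0], [np.log(3) / np.sqrt(2), np.log(3) / np.sqrt(2)]])
        scores = pd.DataFrame([[0.0, 0.0]])
        mem = assign(scores, model)
        assert mem["posterior_1"].iloc[0] == pytest.approx(0.75, abs=1e-9)
        assert mem["posterior_2"].iloc[0] == pytest.approx(0.25, abs=1e-9)
        assert mem["logodds_1"].iloc[0] == pytest.approx(np.log(3), abs=1e-9)
        assert mem["logodds_2"].iloc[0] == pytest.approx(-np.log(3), abs=1e-9)

    def test_equidistant_centres_give_uniform_posterior(self):
        k = 4
        centres = np.zeros((k, 3))
        centres[:, 0] = [1, -1, 0, 0]
        centres[:, 1] = [0, 0, 1, -1]
        model = _model(centres)
        mem = assign(pd.DataFrame([[0.0, 0.0, 0.0]]), model)
        post = posterior_matrix(mem)[0]
        assert post == pytest.approx([0.25] * 4, abs=1e-12)
        assert logodds_matrix(mem)[0] == pytest.approx([-np.log(k - 1)] * 4, abs=1e-9)

    def test_partial_row_assigned_to_nearest_centre_on_observed_dims(self):
        centres = np.array(
            [[5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 9.0, 9.0], [1.0, 2.0, 0.0, 0.0]]
        )
        model = _model(centres)
        scores = pd.DataFrame([[1.0, 2.0, np.nan, np.nan]])
        mem = assign(scores, model)
        # brute-force distances on the two observed coordinates
        obs = np.array([1.0, 2.0])
        dists = np.linalg.norm(centres[:, :2] - obs, axis=1)
        assert mem["hard_label"].iloc[0] == dists.argmin() + 1 == 3

    def test_fully_missing_row_rejected(self):
        model = _model([[0.0, 0.0]])
        with pytest.raises(ClusterError):
            assign(pd.DataFrame([[np.nan, np.nan]]), model)

    def test_posterior_normalization_and_logodds_consistency(self, trajectory_data):
        mem = trajectory_data["reference"]
        post = posterior_matrix(mem)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9
        assert np.abs(expit(logodds_matrix(mem)) - post).max() < 1e-9

    def test_moving_closer_strictly_increases_posterior(self):
        model = _model([[0.0, 0.0], [4.0, 0.0]])
        near = assign(pd.DataFrame([[1.0, 0.0]]), model)["posterior_1"].iloc[0]
        nearer = assign(pd.DataFrame([[0.5, 0.0]]), model)["posterior_1"].iloc[0]
        assert nearer > near


class TestMembershipProperties:
    """Soft-membership algebra holds for arbitrary finite score/centre
    configurations, not just the hand fixtures."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.lists(
                st.floats(min_value=-50, max_value=50, allow_nan=False),
                min_size=3,
                max_size=3,
            ),
            min_size=2,
            max_size=6,
        ),
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=3,
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_posteriors_normalize_and_logodds_invert(self, centres, point):
        model = _model(np.asarray(centres))
        mem = assign(pd.DataFrame([point]), model)
        post = posterior_matrix(mem)
        assert abs(post.sum() - 1.0) < 1e-9
        # open-interval bounds hold mathematically; in floating point a
        # posterior may round to 0 or 1 when centre gaps exceed ~log(1/eps)
        assert (post >= 0).all() and (post <= 1).all()
        assert np.abs(expit(logodds_matrix(mem)) - post).max() < 1e-9


class TestConfidenceFilter:
    @pytest.mark.parametrize(
        "age,posteriors,expected",
        [
            (65.0, [0.10] * 10, True),  # old enough, low confidence: retained
            (45.0, [0.25] * 4, False),  # young, max did not exceed 0.25: excluded
            (45.0, [0.26, 0.26, 0.26, 0.22], True),  # max exceeds 0.25: retained
        ],
    )
    def test_boundary_rules(self, age, posteriors, expected):
        mem = pd.DataFrame(
            {f"posterior_{j + 1}": [p] for j, p in enumerate(posteriors)}, index=["a"]
        )
        ages = pd.Series([age], index=["a"])
        assert confidence_filter(mem, ages).iloc[0] == expected


class TestFederated:
    def test_pooled_counts_reproduce_centralized_model(self, trajectory_data):
        scores = trajectory_data["scores"]
        central = federated_fit([scores], bin_width=0.5, k=7, seed=0)
        split = federated_fit(
            [scores.iloc[:2000], scores.iloc[2000:]], bin_width=0.5, k=7, seed=0
        )
        assert np.array_equal(central.centres, split.centres)

    def test_quantization_close_to_centralized_fit(self, trajectory_data):
        from scipy.optimize import linear_sum_assignment

        scores = trajectory_data["scores"]
        bin_width = 0.25
        fed = federated_fit([scores], bin_width=bin_width, k=7, seed=0)
        direct = trajectory_data["model"]
        d = np.linalg.norm(
            fed.centres[:, None, :] - direct.centres[None, :, :], axis=2
        )
        r, c = linear_sum_assignment(d)
        assert d[r, c].max() <= bin_width * np.sqrt(4)

    def test_refining_bins_converges_to_centralized_fit(self, trajectory_data):
        from scipy.optimize import linear_sum_assignment

        scores = trajectory_data["scores"].iloc[:1500]
        direct = fit_clusters(scores, k=7, seed=0)
        errors = []
        for bin_width in (1.0, 0.25, 0.05):
            fed = federated_fit([scores], bin_width=bin_width, k=7, seed=0)
            d = np.linalg.norm(
                fed.centres[:, None, :] - direct.centres[None, :, :], axis=2
            )
            r, c = linear_sum_assignment(d)
            errors.append(d[r, c].max())
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.05 * np.sqrt(4)

    def test_incompatible_grids_rejected(self):
        a = pd.DataFrame(np.ones((10, 4)), columns=ENDS)
        b = pd.DataFrame(np.ones((10, 3)), columns=ENDS[:3])
        with pytest.raises(ClusterError):
            federated_fit([a, b], bin_width=0.5, k=2)
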