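import numpy as np
import pandas as pd
import pytest
import warnings
from lifelines import CoxPHFitter
from scipy.stats import kstest

from trajectome import (
    CohortTable,
    DiseaseSpec,
    SyntheticConfig,
    adjust_bh,
    age_spline_basis,
    generate_cohort,
    riskfactor_regression,
    weighted_cox,
    weighted_km,
)
from trajectome.outcome_profiles import HazardResult, ProfileError


def _two_group_cohort(n=4000, hr=2.0, seed=5):
    cfg = SyntheticConfig(
        n_participants=n,
        n_clusters=2,
        diseases=(
            DiseaseSpec("X01", (0.004,) * 4, (1.0, hr)),
            DiseaseSpec("F32", (0.002,) * 4, (1.0, 1.0)),
        ),
        target_code="F32",
        censor_age_range=(55.0, 80.0),
        seed=seed,
    )
    return generate_cohort(cfg)


class TestWeightedCox:
    def test_degenerate_posteriors_reproduce_hard_label_fit(self):
        cohort, truth = _two_group_cohort()
        post1 = (truth.labels == 2).astype(float)
        mem = pd.DataFrame(
            {"posterior_1": post1, "posterior_2": 1 - post1},
            index=cohort.participants,
        )
        res = weighted_cox(mem, cohort, "X01", cluster=1, covariates=())
        # hard-split Cox on the same participants
        surv = []
        cov = cohort.covariates.set_index("participant_id")
        hits = cohort.onsets.query("disease_code == 'X01'").set_index(
            "participant_id"
        )["onset_age"]
        frame = pd.DataFrame(index=cov.index)
        frame["duration"] = cov["censor_age"]
        frame["event"] = 0
        frame.loc[hits.index, "duration"] = hits
        frame.loc[hits.index, "event"] = 1
        frame["group"] = post1
        fit = CoxPHFitter().fit(frame, "duration", "event")
        assert np.log(res.hazard_ratio) == pytest.approx(
            float(fit.params_["group"]), abs=1e-8
        )

    def test_uninformative_half_weights_give_null_hazard_ratio(self):
        cohort, _ = _two_group_cohort(n=500)
        mem = pd.DataFrame(
            {"posterior_1": 0.5, "posterior_2": 0.5},
            index=cohort.participants,
        )
        res = weighted_cox(mem, cohort, "X01", cluster=1, covariates=())
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_ci_contains_hazard_ratio(self):
        cohort, truth = _two_group_cohort(n=2000, seed=6)
        post1 = (truth.labels == 2).astype(float)
        mem = pd.DataFrame(
            {"posterior_1": post1, "posterior_2": 1 - post1},
            index=cohort.participants,
        )
        res = weighted_cox(mem, cohort, "X01", cluster=1)
        assert res.ci_lower < res.hazard_ratio < res.ci_upper

    def test_no_events_rejected(self, tiny_cohort):
        mem = pd.DataFrame(
            {"posterior_1": [0.5] * 4}, index=tiny_cohort.participants
        )
        with pytest.raises(ProfileError, match="no events"):
            weighted_cox(mem, tiny_cohort, "Z99", cluster=1)


class TestAdjustBH:
    def _results(self, ps, cohorts=None):
        cohorts = cohorts or ["c"] * len(ps)
        return [
            HazardResult(1, f"D{i}", 1.0, 0.5, 2.0, p, None, 10.0, cohort)
            for i, (p, cohort) in enumerate(zip(ps, cohorts))
        ]

    def test_step_up_arithmetic(self):
        adjusted = adjust_bh(self._results([0.01, 0.02, 0.03]))
        assert [r.p_adjusted for r in adjusted] == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test_unchanged(self):
        adjusted = adjust_bh(self._results([0.04]))
        assert adjusted[0].p_adjusted == pytest.approx(0.04)

    def test_order_invariance(self):
        ps = [0.2, 0.01, 0.6, 0.04]
        direct = {r.disease: r.p_adjusted for r in adjust_bh(self._results(ps))}
        shuffled_idx = [2, 0, 3, 1]
        shuffled = self._results([ps[i] for i in shuffled_idx])
        for r, i in zip(shuffled, shuffled_idx):
            r.disease = f"D{i}"
        back = {r.disease: r.p_adjusted for r in adjust_bh(shuffled)}
        assert direct == pytest.approx(back)

    def test_adjusted_within_cohort_groups(self):
        adjusted = adjust_bh(
            self._results([0.01, 0.02, 0.01, 0.02], ["a", "a", "b", "b"])
        )
        assert [r.p_adjusted for r in adjusted] == pytest.approx(
            [0.02, 0.02, 0.02, 0.02]
        )

    def test_adjusted_at_least_raw(self):
        adjusted = adjust_bh(self._results([0.001, 0.5, 0.9]))
        assert all(r.p_adjusted >= r.p_value for r in adjusted)
        assert all(r.p_adjusted <= 1.0 for r in adjusted)


class TestWeightedKM:
    def test_unit_weights_match_product_limit_by_hand(self, tiny_cohort):
        mem = pd.DataFrame({"posterior_1": [1.0] * 4}, index=tiny_cohort.participants)
        curve = weighted_km(mem, tiny_cohort, "X40", cluster=1)
        lookup = curve.set_index("age")["survival"]
        assert lookup[0.0] == 1.0
        assert lookup[50.0] == pytest.approx(0.75)
        assert lookup[60.0] == pytest.approx(0.5)

    def test_uniform_weight_scaling_invariance(self, tiny_cohort):
        full = weighted_km(
            pd.DataFrame({"posterior_1": [1.0] * 4}, index=tiny_cohort.participants),
            tiny_cohort,
            "X40",
            1,
        )
        half = weighted_km(
            pd.DataFrame({"posterior_1": [0.5] * 4}, index=tiny_cohort.participants),
            tiny_cohort,
            "X40",
            1,
        )
        pd.testing.assert_frame_equal(full, half)

    def test_curve_bounded_and_monotone(self):
        cohort, truth = _two_group_cohort(n=800)
        post = np.where(truth.labels == 2, 0.9, 0.2)
        mem = pd.DataFrame({"posterior_1": post}, index=cohort.participants)
        curve = weighted_km(mem, cohort, "X01", 1)
        s = curve["survival"].to_numpy()
        assert ((0 <= s) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_no_events_survival_is_one(self, tiny_cohort):
        mem = pd.DataFrame({"posterior_1": [1.0] * 4}, index=tiny_cohort.participants)
        curve = weighted_km(mem, tiny_cohort, "Z99", 1)
        assert (curve["survival"] == 1.0).all()


class TestRiskFactorRegression:
    def _memberships(self, logodds, index):
        from scipy.special import expit

        post = expit(np.asarray(logodds))
        return pd.DataFrame(
            {"posterior_1": post, "logodds_1": logodds}, index=index
        )

    def test_self_regression_recovers_unit_coefficient(self):
        rng = np.random.default_rng(0)
        n = 400
        idx = pd.RangeIndex(n)
        logodds = rng.normal(size=n)
        ages = pd.Series(rng.uniform(30, 80, n), index=idx)
        sex = pd.Series(rng.integers(0, 2, n), index=idx)
        # orthogonalize the outcome against age and sex so the factor,
        # which equals the residualized outcome, must get coefficient 1
        basis = np.column_stack(
            [np.ones(n), age_spline_basis(ages.to_numpy()), sex.to_numpy()]
        )
        resid = logodds - basis @ np.linalg.lstsq(basis, logodds, rcond=None)[0]
        mem = self._memberships(resid, idx)
        factors = pd.DataFrame({"factor": resid}, index=idx)
        results = riskfactor_regression(mem, factors, ages, sex, mode="simple")
        coef = results[0].coefficient
        assert coef == pytest.approx(1.0, abs=1e-6)

    def test_null_factor_pvalues_uniform(self):
        n = 120
        idx = pd.RangeIndex(n)
        ps = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            mem = self._memberships(rng.normal(size=n), idx)
            factors = pd.DataFrame({"noise": rng.normal(size=n)}, index=idx)
            ages = pd.Series(rng.uniform(30, 80, n), index=idx)
            sex = pd.Series(rng.integers(0, 2, n), index=idx)
            res = riskfactor_regression(mem, factors, ages, sex, mode="simple")
            ps.append(res[0].p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_effect_recovered_by_complex_mode(self):
        rng = np.random.default_rng(3)
        n = 2000
        idx = pd.RangeIndex(n)
        factor = rng.normal(size=n)
        other = rng.normal(size=n)
        logodds = 0.3 * factor + rng.normal(scale=1.0, size=n)
        mem = self._memberships(logodds, idx)
        factors = pd.DataFrame({"factor": factor, "other": other}, index=idx)
        factors.loc[: n // 10, "other"] = np.nan  # exercise kNN imputation
        ages = pd.Series(rng.uniform(30, 80, n), index=idx)
        sex = pd.Series(rng.integers(0, 2, n), index=idx)
        res = riskfactor_regression(mem, factors, ages, sex, mode="complex")
        by_name = {r.factor: r for r in res}
        expected = 0.3 / logodds.std()
        assert by_name["factor"].coefficient == pytest.approx(expected, abs=0.06)
        assert by_name["factor"].p_adjusted <= 1.0

    def test_zero_variance_factor_skipped_with_warning(self):
        n = 100
        idx = pd.RangeIndex(n)
        rng = np.random.default_rng(4)
        mem = self._memberships(rng.normal(size=n), idx)
        factors = pd.DataFrame(
            {"flat": np.ones(n), "ok": rng.normal(size=n)}, index=idx
        )
        ages = pd.Series(rng.uniform(30, 80, n), index=idx)
        sex = pd.Series(rng.integers(0, 2, n), index=idx)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = riskfactor_regression(mem, factors, ages, sex, mode="simple")
        assert {r.factor for r in res} == {"ok"}

    def test_bonferroni_is_p_times_m_capped(self):
        n = 300
        idx = pd.RangeIndex(n)
        rng = np.random.default_rng(5)
        mem = self._memberships(rng.normal(size=n), idx)
        factors = pd.DataFrame(
            {f"f{i}": rng.normal(size=n) for i in range(4)}, index=idx
        )
        ages = pd.Series(rng.uniform(30, 80, n), index=idx)
        sex = pd.Series(rng.integers(0, 2, n), index=idx)
        res = riskfactor_regression(mem, factors, ages, sex, mode="simple")
        m = len(res)
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * m))


class TestAgeSpline:
    def test_knot_outside_observed_range_dropped(self):
        ages = np.linspace(45, 80, 100)
        basis_full = age_spline_basis(ages, knots=(40.0, 60.0))
        basis_single = age_spline_basis(ages, knots=(60.0,))
        assert basis_full.shape == basis_single.shape
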