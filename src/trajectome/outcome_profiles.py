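"""Clinical profiling of trajectory clusters.

Disease profiles use a duplicated-row weighted Cox design: every participant
enters each per-cluster model twice, once with cluster-dummy 1 weighted by
their posterior membership probability and once with dummy 0 weighted by the
complement, so the two rows sum to weight 1.  The time axis is age; a
participant without the outcome disease is right-censored at their censoring
age.  Cluster-specific disease-free survival uses posterior-weighted
Kaplan-Meier curves.  Risk-factor profiles regress the posterior membership
log-odds on each factor (one at a time with an age spline and sex — "simple"
mode) or on all factors jointly after k-nearest-neighbour imputation
("complex" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import StatisticalWarning
from scipy.interpolate import BSpline
from sklearn.impute import KNNImputer
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .cluster_engine import logodds_matrix
from .cohort_io import CohortTable


class ProfileError(ValueError):
    pass


@dataclass
class HazardResult:
    cluster: int
    disease: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    p_adjusted: float | None
    n_effective: float
    cohort: str = "cohort"


@dataclass
class RiskFactorResult:
    cluster: int
    factor: str
    coefficient: float
    p_value: float
    p_adjusted: float | None
    model: str  # "simple" | "complex"


def _survival_frame(
    cohort: CohortTable, disease: str
) -> pd.DataFrame:
    """Per participant: age at first onset of ``disease`` (event) or censoring
    age (no event)."""
    cov = cohort.covariates.set_index("participant_id")
    onsets = cohort.onsets
    hits = onsets[onsets["disease_code"] == disease].set_index("participant_id")[
        "onset_age"
    ]
    frame = pd.DataFrame(index=cov.index)
    frame["duration"] = cov["censor_age"]
    frame["event"] = 0
    frame.loc[hits.index, "duration"] = hits
    frame.loc[hits.index, "event"] = 1
    frame["sex"] = cov["sex"]
    frame["income"] = cov["income"]
    by = cov["birth_year"].astype(float)
    sd = by.std(ddof=0)
    frame["birth_year_norm"] = (by - by.mean()) / sd if sd > 0 else 0.0
    return frame


def weighted_cox(
    memberships: pd.DataFrame,
    cohort: CohortTable,
    disease: str,
    cluster: int,
    covariates: tuple[str, ...] = ("sex", "income", "birth_year_norm"),
    robust: bool = False,
    cohort_label: str = "cohort",
) -> HazardResult:
    """Duplicated-row weighted Cox model for one cluster and one disease.

    The hazard ratio is exp(coefficient) of the cluster dummy in an
    Efron-ties partial-likelihood fit with case weights; the CI is Wald on
    the log scale (sandwich SEs when ``robust``)."""
    post = memberships[f"posterior_{cluster}"]
    surv = _survival_frame(cohort, disease).loc[memberships.index]
    if surv["event"].sum() == 0:
        raise ProfileError(f"no events for disease {disease!r}")
    w1 = post.to_numpy(dtype=float)
    if not np.all(np.isfinite(w1)):
        raise ProfileError("non-finite membership weights")
    rows = []
    for dummy, weight in ((1.0, w1), (0.0, 1.0 - w1)):
        part = surv.copy()
        part["cluster_dummy"] = dummy
        part["weight"] = weight
        rows.append(part)
    stacked = pd.concat(rows, ignore_index=True)
    stacked = stacked[stacked["weight"] > 0]
    keep = ["duration", "event", "cluster_dummy", "weight", *covariates]
    usable = [
        c
        for c in keep
        if c in ("duration", "event", "cluster_dummy", "weight")
        or stacked[c].nunique() > 1
    ]
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        fitter.fit(
            stacked[usable],
            duration_col="duration",
            event_col="event",
            weights_col="weight",
            robust=robust,
        )
    coef = float(fitter.params_["cluster_dummy"])
    se = float(fitter.standard_errors_["cluster_dummy"])
    p = float(fitter.summary.loc["cluster_dummy", "p"])
    z = 1.959963984540054
    return HazardResult(
        cluster=cluster,
        disease=disease,
        hazard_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_value=p,
        p_adjusted=None,
        n_effective=float(stacked["weight"].sum()),
        cohort=cohort_label,
    )


def adjust_bh(results: list[HazardResult]) -> list[HazardResult]:
    """Benjamini-Hochberg adjustment of the Cox p-values, applied separately
    within each cohort group."""
    out: list[HazardResult] = []
    frame = pd.DataFrame(
        {"cohort": [r.cohort for r in results], "p": [r.p_value for r in results]}
    )
    adjusted = np.empty(len(results))
    for _, idx in frame.groupby("cohort").groups.items():
        idx = np.asarray(idx)
        adjusted[idx] = multipletests(frame.loc[idx, "p"], method="fdr_bh")[1]
    for r, p_adj in zip(results, adjusted):
        out.append(replace(r, p_adjusted=float(p_adj)))
    return out


def weighted_km(
    memberships: pd.DataFrame,
    cohort: CohortTable,
    disease: str,
    cluster: int,
) -> pd.DataFrame:
    """Posterior-weighted Kaplan-Meier curve of disease-free survival for one
    cluster: product-limit estimator with risk sets and event counts weighted
    by the posterior membership probability."""
    post = memberships[f"posterior_{cluster}"].to_numpy(dtype=float)
    if post.sum() <= 0:
        raise ProfileError("total membership weight is zero")
    surv = _survival_frame(cohort, disease).loc[memberships.index]
    km = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        km.fit(surv["duration"], surv["event"], weights=post)
    curve = km.survival_function_.reset_index()
    curve.columns = ["age", "survival"]
    return curve


# ---------------------------------------------------------------------------
# Risk-factor regressions
# ---------------------------------------------------------------------------


def age_spline_basis(
    ages: np.ndarray, knots: tuple[float, ...] = (40.0, 60.0)
) -> np.ndarray:
    """Cubic B-spline basis for age with the given interior knots; knots
    outside the observed age span are dropped (single-knot fallback), and
    with no usable knot the basis degenerates to a plain cubic polynomial
    basis."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = ages.min(), ages.max()
    usable = [k for k in knots if lo < k < hi]
    degree = 3
    t = np.r_[[lo] * (degree + 1), usable, [hi] * (degree + 1)]
    design = BSpline.design_matrix(np.clip(ages, lo, hi), t, degree).toarray()
    return design[:, 1:]  # drop one column: the basis sums to 1


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def riskfactor_regression(
    memberships: pd.DataFrame,
    factors: pd.DataFrame,
    ages: pd.Series,
    sex: pd.Series,
    mode: str = "simple",
    knots: tuple[float, ...] = (40.0, 60.0),
    knn_neighbors: int = 5,
) -> list[RiskFactorResult]:
    """Linear models of the standardized posterior log-odds per cluster.

    ``simple``: one factor at a time, adjusted for an age spline and sex,
    complete cases only.  ``complex``: all factors jointly after kNN
    imputation of missing factor values.  Continuous variables are
    standardized; p-values are two-sided t-tests with Bonferroni adjustment
    over factor-by-cluster tests.
    """
    if mode not in ("simple", "complex"):
        raise ProfileError("mode must be 'simple' or 'complex'")
    logodds = logodds_matrix(memberships)
    k = logodds.shape[1]
    idx = memberships.index
    ages = ages.loc[idx].to_numpy(dtype=float)
    sex_arr = sex.loc[idx].to_numpy(dtype=float)
    factors = factors.loc[idx]
    factor_names = []
    for name in factors.columns:
        col = factors[name].dropna()
        if col.nunique() <= 1:
            warnings.warn(f"skipping zero-variance factor {name!r}", stacklevel=2)
            continue
        factor_names.append(name)
    results: list[RiskFactorResult] = []
    spline = age_spline_basis(ages, knots)
    base = np.column_stack([np.ones(len(idx)), spline, sex_arr])

    if mode == "complex":
        imputed = KNNImputer(n_neighbors=knn_neighbors).fit_transform(
            factors[factor_names].to_numpy(dtype=float)
        )
        x_fact = np.column_stack([_standardize(imputed[:, j]) for j in range(len(factor_names))])
        design = np.column_stack([base, x_fact])
        for j in range(k):
            y = _standardize(logodds[:, j])
            fit = OLS(y, design).fit()
            for fi, name in enumerate(factor_names):
                col = base.shape[1] + fi
                results.append(
                    RiskFactorResult(
                        cluster=j + 1,
                        factor=name,
                        coefficient=float(fit.params[col]),
                        p_value=float(fit.pvalues[col]),
                        p_adjusted=None,
                        model="complex",
                    )
                )
    else:
        for name in factor_names:
            col = factors[name].to_numpy(dtype=float)
            complete = ~np.isnan(col)
            x = _standardize(col[complete])
            design = np.column_stack([base[complete], x])
            for j in range(k):
                y = _standardize(logodds[complete, j])
                fit = OLS(y, design).fit()
                results.append(
                    RiskFactorResult(
                        cluster=j + 1,
                        factor=name,
                        coefficient=float(fit.params[-1]),
                        p_value=float(fit.pvalues[-1]),
                        p_adjusted=None,
                        model="simple",
                    )
                )
    m = len(results)
    return [
        replace(r, p_adjusted=min(1.0, r.p_value * m)) for r in results
    ]


def hazard_results_frame(results: list[HazardResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def riskfactor_results_frame(results: list[RiskFactorResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
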