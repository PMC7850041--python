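"""Propensity-score cohort matching with balance diagnostics.

Case membership is modelled with a logistic GLM on the demographic and
coverage covariates; each case is then greedily assigned its
``match_ratio`` nearest-propensity controls, without replacement and
with exact agreement required on handedness (a proxy for hemispheric
dominance).  Balance is summarized by standardized mean differences and
two-sample tests before versus after matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import COHORT_DESIGN_COLUMNS, cohort_design_matrix

__all__ = [
    "fit_propensity",
    "match_controls",
    "balance_table",
]


def fit_propensity(cohort: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Fit the propensity model and return (scores, coefficients).

    The model is a binomial GLM of ``group == 'case'`` on the
    standardized covariate design; fitted probabilities are strictly
    inside (0, 1).  Quasi-separation is flagged with a warning rather
    than an error.
    """
    if set(cohort["group"].unique()) != {"case", "control"}:
        raise ValueError("cohort must contain both 'case' and 'control' subjects")
    design = cohort_design_matrix(cohort)
    # constant covariates carry no information and break the IRLS fit
    design = design.loc[:, design.std(axis=0) > 1e-9]
    X = sm.add_constant(design, has_constant="add")
    if X.isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")
    y = (cohort["group"] == "case").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    p = res.fittedvalues
    if (p < 1e-8).any() or (p > 1 - 1e-8).any():
        warnings.warn("near-perfect separation in the propensity model")
    scores = pd.Series(np.clip(p, 1e-12, 1 - 1e-12).to_numpy(),
                       index=cohort.index, name="propensity")
    return scores, res.params


def match_controls(
    cohort: pd.DataFrame,
    match_ratio: int = 3,
    scale: str = "probability",
) -> pd.DataFrame:
    """Select ``match_ratio`` controls per case by nearest propensity.

    Cases are processed in descending propensity order (hardest to
    match first); for each, the nearest unused controls with identical
    handedness are taken, distances on the probability scale by default
    (``scale='logit'`` for logit distance), ties broken by subject id.
    Returns the cohort with ``propensity`` and ``matched_to`` columns;
    cases that cannot be fully matched keep partial assignments and are
    flagged with a warning.
    """
    cohort = cohort.reset_index(drop=True).copy()
    scores, _ = fit_propensity(cohort)
    cohort["propensity"] = scores.to_numpy()
    cohort["matched_to"] = pd.array([pd.NA] * len(cohort), dtype="string")
    if scale == "logit":
        d_score = np.log(cohort["propensity"] / (1 - cohort["propensity"]))
    elif scale == "probability":
        d_score = cohort["propensity"].copy()
    else:
        raise ValueError(f"unknown distance scale {scale!r}")
    cohort["_dist_score"] = d_score

    cases = cohort[cohort["group"] == "case"].sort_values(
        ["propensity", "subject"], ascending=[False, True]
    )
    used: set[int] = set()
    shortfall = []
    for idx, case in cases.iterrows():
        pool = cohort[
            (cohort["group"] == "control")
            & (cohort["handedness"] == case["handedness"])
            & (~cohort.index.isin(used))
        ]
        dist = (pool["_dist_score"] - case["_dist_score"]).abs()
        order = pool.assign(_d=dist).sort_values(["_d", "subject"])
        take = order.index[:match_ratio]
        for j in take:
            cohort.loc[j, "matched_to"] = case["subject"]
            used.add(j)
        if len(take) < match_ratio:
            shortfall.append((case["subject"], len(take)))
    if shortfall:
        warnings.warn(f"insufficient compatible controls for cases: {shortfall}")
    return cohort.drop(columns="_dist_score")


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD denominator."""
    sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if sd == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sd)


def balance_table(matched: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate balance before and after matching.

    For every model covariate, reports the standardized mean difference
    and a Welch t-test p-value for case versus *all* controls (before)
    and case versus *matched* controls (after).
    """
    if matched["matched_to"].notna().sum() == 0:
        raise ValueError("no matched controls; balance undefined")
    X = cohort_design_matrix(matched)
    case = X[matched["group"] == "case"]
    ctrl_all = X[matched["group"] == "control"]
    ctrl_m = X[(matched["group"] == "control") & matched["matched_to"].notna()]
    rows = []
    for col in COHORT_DESIGN_COLUMNS:
        a = case[col].to_numpy(dtype=float)
        rec = {"covariate": col,
               "smd_before": _smd(a, ctrl_all[col].to_numpy(dtype=float)),
               "smd_after": _smd(a, ctrl_m[col].to_numpy(dtype=float))}
        for tag, other in (("before", ctrl_all), ("after", ctrl_m)):
            b = other[col].to_numpy(dtype=float)
            if a.std() == 0 and b.std() == 0:
                rec[f"p_{tag}"] = 1.0
            else:
                rec[f"p_{tag}"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(rec)
    return pd.DataFrame(rows)
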