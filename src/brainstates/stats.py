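"""Condition contrasts and covariate regressions for dynamics metrics.

Rest-vs-task differences in per-subject metrics are tested with paired
t-tests, Bonferroni-corrected within each metric family (the k states, or
the k(k-1) transitions). Developmental and behavioral associations use
ordinary least squares:

    D = b0 + b_a*age + b_v*volume + b_h*handedness + b_m*meanFD + b_s*sex
    C = b0 + b_D*D + (same covariates)

where D is a dynamics metric (fractional occupancy, dwell time, transition
probability, transition energy) and C is the d' working-memory score.
Reported coefficients are standardized: the outcome and all continuous
predictors are z-scored before fitting; sex stays 0/1 so its coefficient is
a per-category effect in outcome standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "bonferroni_correct",
    "paired_contrast",
    "PairedContrast",
    "fit_dynamics_regression",
    "fit_performance_regression",
    "COVARIATE_COLUMNS",
]

#: covariates entering every regression; sex is binary, the rest continuous
COVARIATE_COLUMNS = ("age", "volume", "handedness", "mean_fd", "sex")
_CONTINUOUS = ("age", "volume", "handedness", "mean_fd")


def bonferroni_correct(pvals: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni correction: min(1, p * m)."""
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    return np.minimum(np.asarray(pvals, float) * m, 1.0) if np.ndim(pvals) else min(
        float(pvals) * m, 1.0
    )


@dataclass
class PairedContrast:
    mean_diff: float  # task - rest
    t: float
    df: int
    p: float
    p_corrected: float
    degenerate: bool = False


def paired_contrast(
    metric_rest: np.ndarray, metric_task: np.ndarray, m: int = 1
) -> PairedContrast:
    """Paired t-test on task - rest subject differences.

    ``m`` is the Bonferroni family size (e.g. the k states of one metric
    family). Zero variance of the differences is flagged as degenerate.
    """
    rest = np.asarray(metric_rest, float)
    task = np.asarray(metric_task, float)
    if rest.shape != task.shape or rest.ndim != 1:
        raise ValidationError("paired contrast needs equal-length 1-D arrays")
    n = rest.size
    if n < 3:
        raise ValidationError("paired contrast needs n >= 3")
    diff = task - rest
    if np.allclose(diff.std(ddof=1), 0.0):
        mean = float(diff.mean())
        if mean == 0.0:
            # identical metrics: no effect, p = 1 by convention
            return PairedContrast(0.0, 0.0, n - 1, 1.0, 1.0, degenerate=True)
        return PairedContrast(mean, np.inf, n - 1, 0.0, 0.0, degenerate=True)
    res = sps.ttest_rel(task, rest)
    p = float(res.pvalue)
    return PairedContrast(
        mean_diff=float(diff.mean()),
        t=float(res.statistic),
        df=n - 1,
        p=p,
        p_corrected=float(bonferroni_correct(p, m)),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def _design(cov: pd.DataFrame, extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    if cov[list(COVARIATE_COLUMNS)].isna().any().any():
        raise ValidationError("covariate table contains missing values")
    X = pd.DataFrame(index=cov.index)
    if extra:
        for name, vals in extra.items():
            X[name] = _zscore(np.asarray(vals, float))
    for c in _CONTINUOUS:
        X[c] = _zscore(cov[c].to_numpy(float))
    X["sex"] = cov["sex"].to_numpy(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(M) == M.shape[1]:
        return
    # identify columns explained by the others
    cols = list(X.columns)
    collinear = []
    for j, name in enumerate(cols):
        others = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(float) for c in cols if c != name]
        )
        y = X[name].to_numpy(float)
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        if np.allclose(resid, 0.0, atol=1e-10):
            collinear.append(name)
    raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")


def _fit_ols(y: np.ndarray, X: pd.DataFrame, m: int) -> pd.DataFrame:
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(float))
    model = sm.OLS(_zscore(np.asarray(y, float)), design).fit()
    names = ["const"] + list(X.columns)
    out = pd.DataFrame(
        {
            "predictor": names,
            "beta": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "df": int(model.df_resid),
            "p": model.pvalues,
            "family_m": m,
        }
    )
    out["p_corrected"] = bonferroni_correct(out["p"].to_numpy(), m)
    return out.reset_index(drop=True)


def fit_dynamics_regression(
    D: np.ndarray, cov: pd.DataFrame, m: int = 1
) -> pd.DataFrame:
    """Standardized OLS of a dynamics metric on age plus confounders.

    Rows are subjects. Returns one row per predictor with standardized beta,
    SE, t, p, and Bonferroni-corrected p (family size ``m``; e.g. k = 5
    states or k(k-1) = 20 transitions).
    """
    D = np.asarray(D, float)
    cov = cov.reset_index(drop=True)
    if D.shape[0] != len(cov):
        raise ValidationError("metric and covariate table disagree on n")
    if np.isnan(D).any():
        raise ValidationError("metric contains missing values; filter rows first")
    X = _design(cov)
    if len(cov) <= X.shape[1] + 1:
        raise ValidationError("need more subjects than predictors")
    return _fit_ols(D, X, m)


def fit_performance_regression(
    C: np.ndarray, D: np.ndarray, cov: pd.DataFrame, m: int = 1
) -> pd.DataFrame:
    """Standardized OLS of task performance (d') on a dynamics metric.

    The metric of interest D enters as predictor ``"D"`` alongside the same
    confounders as :func:`fit_dynamics_regression`.
    """
    C = np.asarray(C, float)
    D = np.asarray(D, float)
    cov = cov.reset_index(drop=True)
    if not (C.shape[0] == D.shape[0] == len(cov)):
        raise ValidationError("C, D, and covariates disagree on n")
    if np.isnan(C).any() or np.isnan(D).any():
        raise ValidationError("inputs contain missing values; filter rows first")
    X = _design(cov, extra={"D": D})
    if len(cov) <= X.shape[1] + 1:
        raise ValidationError("need more subjects than predictors")
    return _fit_ols(C, X, m)
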