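"""Multiple imputation by predictive mean matching (PMM).

Each missing cell is filled with an *observed* value of the same variable,
donated by one of the ``k`` complete rows whose linear-model prediction is
closest to the prediction for the incomplete row.  Because donors are real
observations, imputed values always stay on the variable's support.

``pmm_impute`` produces ``m`` independently seeded completions (chained
passes over the variables, coefficients perturbed with a posterior-style
normal draw per completion so the imputations differ); pooling across
completions follows Rubin's rules for means.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["pmm_impute", "pool_means"]


def _impute_once(
    df: pd.DataFrame,
    variables: list[str],
    predictors: dict[str, list[str]],
    k_donors: int,
    rng: np.random.Generator,
    n_iter: int,
) -> pd.DataFrame:
    work = df.copy()
    miss = {v: df[v].isna().to_numpy() for v in variables}
    # initial fill: random observed donors
    for v in variables:
        obs = df.loc[~miss[v], v].to_numpy(dtype=float)
        if len(obs) == 0:
            raise ValueError(f"variable {v!r} has no observed values")
        if miss[v].any():
            work.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))
    for _ in range(n_iter):
        for v in variables:
            m = miss[v]
            if not m.any():
                continue
            preds = predictors[v]
            X = np.column_stack(
                [np.ones(len(work))]
                + [work[p].to_numpy(dtype=float) for p in preds]
            )
            y_obs = df.loc[~m, v].to_numpy(dtype=float)
            X_obs = X[~m]
            XtX = X_obs.T @ X_obs
            XtX += 1e-8 * np.eye(XtX.shape[0]) * np.trace(XtX) / XtX.shape[0]
            beta = np.linalg.solve(XtX, X_obs.T @ y_obs)
            resid = y_obs - X_obs @ beta
            dof = max(len(y_obs) - len(beta), 1)
            sigma2 = float(resid @ resid) / dof
            # posterior-style draw so the m completions differ
            cov = np.linalg.inv(XtX) * sigma2
            beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
            yhat_obs = X_obs @ beta_star
            yhat_mis = X[m] @ beta_star
            k = min(k_donors, len(y_obs))
            filled = np.empty(len(yhat_mis))
            for i, pred in enumerate(yhat_mis):
                idx = np.argsort(np.abs(yhat_obs - pred), kind="stable")[:k]
                filled[i] = y_obs[idx[rng.integers(k)]]
            work.loc[m, v] = filled
    return work


def pmm_impute(
    data: pd.DataFrame,
    m: int = 10,
    k_donors: int = 5,
    seed: int = 0,
    variables: Optional[Sequence[str]] = None,
    n_iter: int = 3,
) -> list[pd.DataFrame]:
    """Generate ``m`` PMM-completed copies of ``data``.

    Parameters
    ----------
    data
        One row per participant; numeric columns may contain NaN.
    m
        Number of completed datasets.
    k_donors
        Donor-pool size for the matching step.
    variables
        Columns to use as the joint imputation model (targets and
        predictors alike); defaults to every numeric column.  Observed
        cells are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    variables = list(variables)
    for v in variables:
        if v not in data.columns:
            raise KeyError(f"unknown column {v!r}")
    predictors = {v: [p for p in variables if p != v] for v in variables}
    seeds = np.random.SeedSequence(seed).spawn(m)
    completions = []
    for s in seeds:
        rng = np.random.default_rng(s)
        completions.append(
            _impute_once(data, variables, predictors, k_donors, rng, n_iter)
        )
    return completions


def pool_means(completions: Sequence[pd.DataFrame], column: str) -> dict:
    """Rubin's rules for the mean of one variable across completions.

    Returns the pooled estimate, the within- and between-imputation
    variances and the total variance of the pooled mean.
    """
    m = len(completions)
    means = np.array([c[column].mean() for c in completions])
    within = np.array(
        [c[column].var(ddof=1) / len(c) for c in completions]
    ).mean()
    between = means.var(ddof=1) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    return {
        "estimate": float(means.mean()),
        "within_var": float(within),
        "between_var": float(between),
        "total_var": float(total),
    }
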