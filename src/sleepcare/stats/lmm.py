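"""Two-level random-intercept linear models fitted by maximum likelihood.

The model for observation *t* of participant *j* is

    y_jt = x_jt' beta + u_j + e_jt,   u_j ~ N(0, sigma_u^2),  e_jt ~ N(0, sigma_e^2)

Estimation profiles the likelihood over the variance ratio
``theta = sigma_u^2 / sigma_e^2``: for a fixed theta, the GLS estimate of
``beta`` and the residual variance are available in closed form (the
per-group covariance ``I + theta * J`` has an analytic inverse and
determinant), leaving a one-dimensional deterministic optimization over
theta.  Full ML (not REML) is used throughout so that likelihood-ratio
chi-squares between models differing in their fixed effects are valid.

Likelihood-ratio comparison of two nested fits also reports a level-1 R²:
the proportional reduction in residual (within-participant) variance
relative to the null model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as _chi2

__all__ = ["FitResult", "ModelComparison", "fit_random_intercept", "compare_models"]

_THETA_MAX = 1e4
_XTOL = 1e-12


@dataclass(frozen=True)
class FitResult:
    """A fitted random-intercept model."""

    params: pd.Series  # fixed coefficients, indexed by term name
    bse: pd.Series  # standard errors
    sigma2_e: float  # level-1 residual variance
    sigma2_u: float  # random-intercept variance
    loglik: float
    n_obs: int
    n_participants: int
    terms: tuple[str, ...]

    @property
    def n_parameters(self) -> int:
        """Fixed coefficients plus the two variance components."""
        return len(self.params) + 2

    def pvalues(self) -> pd.Series:
        """Wald z-test p-values for the fixed coefficients."""
        from scipy.stats import norm

        z = self.params / self.bse
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.params, "SE": self.bse, "p": self.pvalues()}
        )


@dataclass(frozen=True)
class ModelComparison:
    chi_square: float
    df: int
    p_value: float
    r2_level1: float


class _ProfileData:
    """Sufficient statistics for the profile likelihood over the variance ratio.

    For V_j = I + theta*J the Woodbury identity gives
    X'V⁻¹X = X'X − Σ_j c_j (Σx_j)(Σx_j)' with c_j = theta/(1+n_j theta),
    so only total cross-products and per-group sums are needed — each theta
    evaluation is O(G·p²) regardless of n.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, starts: np.ndarray):
        self.n = len(y)
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        self.sx = np.add.reduceat(X, starts[:-1], axis=0)  # G x p group sums
        self.sy = np.add.reduceat(y, starts[:-1])
        self.nj = np.diff(starts).astype(float)

    def loglik(self, theta: float):
        c = theta / (1.0 + self.nj * theta)
        xtvx = self.xtx - (self.sx * c[:, None]).T @ self.sx
        xtvy = self.xty - self.sx.T @ (c * self.sy)
        ytvy = self.yty - float(c @ (self.sy * self.sy))
        logdet = float(np.log1p(self.nj * theta).sum())
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta
        sigma2 = max(rss / self.n, 1e-300)
        ll = -0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdet + self.n)
        return ll, beta, sigma2, xtvx


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str = "value",
    fixed: Sequence[str] = (),
    group: str = "participant",
) -> FitResult:
    """Fit a random-intercept model by full maximum likelihood.

    Parameters
    ----------
    data
        One row per observation.  Must contain the ``outcome`` column, the
        ``group`` column identifying participants, and a numeric column for
        every term in ``fixed``.  Interaction terms are written
        ``"a:b"`` and built as the product of the two columns.
    outcome
        Name of the response column.
    fixed
        Fixed-effect terms beyond the intercept (the intercept is always
        included).  Participants with a single observation are retained:
        they still inform the fixed effects and the variance components.

    The fit is deterministic: a bounded scalar profile-likelihood search
    over the variance ratio to tolerance ~1e-12, with the OLS boundary
    (zero intercept variance) checked explicitly.
    """
    cols = [outcome, group]
    base_terms = sorted({t for term in fixed for t in term.split(":")})
    cols += [c for c in base_terms if c in data.columns]
    sub = data.dropna(subset=[outcome]).copy()
    if len(sub) == 0:
        raise ValueError("no observations")
    sub = sub.sort_values(group, kind="stable")
    y = sub[outcome].to_numpy(dtype=float)
    design_cols = [np.ones(len(sub))]
    names = ["intercept"]
    for term in fixed:
        parts = term.split(":")
        col = np.ones(len(sub))
        for partname in parts:
            if partname not in sub.columns:
                raise KeyError(f"fixed term {term!r}: column {partname!r} missing")
            col = col * sub[partname].to_numpy(dtype=float)
        design_cols.append(col)
        names.append(term)
    X = np.column_stack(design_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    codes, _uniques = pd.factorize(sub[group].to_numpy())
    # groups are contiguous after the stable sort
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change, [len(codes)]])
    n_groups = len(starts) - 1
    if n_groups < 2:
        raise ValueError("need at least 2 participants")

    prof = _ProfileData(y, X, starts)
    neg = lambda th: -prof.loglik(th)[0]  # noqa: E731
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, _THETA_MAX), method="bounded",
        options={"xatol": _XTOL},
    )
    theta = float(res.x)
    if neg(0.0) <= res.fun:  # boundary: no between-participant variance
        theta = 0.0
    ll, beta, sigma2_e, xtvx = prof.loglik(theta)
    cov_beta = np.linalg.inv(xtvx) * sigma2_e
    se = np.sqrt(np.diag(cov_beta))
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        sigma2_e=float(sigma2_e),
        sigma2_u=float(theta * sigma2_e),
        loglik=float(ll),
        n_obs=len(y),
        n_participants=n_groups,
        terms=tuple(names),
    )


def compare_models(null: FitResult, full: FitResult) -> ModelComparison:
    """Likelihood-ratio comparison of two nested fits on the same data.

    ``chi2 = 2 (ll_full − ll_null)`` with df the difference in fixed
    coefficients.  ``r2_level1`` is the proportional reduction in level-1
    residual variance relative to the null; it can be negative and is
    reported as computed.
    """
    if null.n_obs != full.n_obs:
        raise ValueError("models were fitted on different data")
    if not set(null.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    df = len(full.terms) - len(null.terms)
    chi = 2.0 * (full.loglik - null.loglik)
    if -1e-8 < chi < 0:
        chi = 0.0
    p = float(_chi2.sf(chi, df)) if df > 0 else 1.0
    r2 = 1.0 - full.sigma2_e / null.sigma2_e if null.sigma2_e > 0 else 0.0
    return ModelComparison(chi_square=float(chi), df=df, p_value=p, r2_level1=float(r2))
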