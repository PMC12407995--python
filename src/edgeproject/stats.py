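"""Mass-univariate OLS core and multiple-testing correction.

Every association test in the package has the same form: an outcome is
regressed on a shared covariate design matrix plus one scalar regressor of
interest (an edge correlation, a group indicator, or a state occupancy
rate), and the reported tuple (beta, SE, t, p, partial r) describes that
single term.

Fitting thousands of such models per cohort, per permutation and per
bootstrap draw is the computational workhorse, so the implementation uses
the Frisch-Waugh-Lovell reduction: outcome and regressors are residualized
against the covariates once (via a thin QR of the design), after which each
edge model is a simple regression.  This is algebraically identical to the
full OLS fit — the test suite checks agreement with statsmodels to 1e-8 —
but runs as two matrix products.

The effect-size correlate reported alongside beta is the partial
correlation recovered from the t statistic, r = sign(t) * sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["bh_fdr", "fit_edge_glm", "EdgeGLMFit", "batch_edge_glm", "ResidualizedDesign"]

# residual sums of squares below this (relative) level are treated as exact fits
_RSS_TOL = 1e-12


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Rejecting tests with q <= alpha reproduces the classic step-up rule at
    level alpha.  NaN entries are an error: callers decide explicitly which
    tests belong to the family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values: remove skipped tests from the family first")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ResidualizedDesign:
    """Covariate design residualizer shared across edges and permutations.

    Holds the thin-QR factor Q of the (full-rank) design matrix; residualizing
    any vector or matrix against the covariates is ``M - Q @ (Q.T @ M)``.
    """

    Q: np.ndarray
    n: int
    p: int  # columns (rank) of the design, including intercept

    @classmethod
    def from_design(cls, X) -> "ResidualizedDesign":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need more subjects ({n}) than design columns + 1 ({p + 1})")
        Q, R = np.linalg.qr(X)
        if np.abs(np.diag(R)).min() <= 1e-10 * np.abs(np.diag(R)).max():
            raise ValueError("design matrix is rank deficient")
        return cls(Q=Q, n=n, p=p)

    @property
    def df_resid(self) -> int:
        """Residual degrees of freedom of the edge model: n - p - 1."""
        return self.n - self.p - 1

    def residualize(self, M: np.ndarray) -> np.ndarray:
        return M - self.Q @ (self.Q.T @ M)


@dataclass
class EdgeGLMFit:
    """Single-regressor OLS summary for the term of interest."""

    beta: float
    se: float
    t: float
    p: float
    partial_r: float
    df: int


def _finalize(beta, ee, rss_edge, yr_ss, df):
    """Turn FWL sufficient statistics into (se, t, p, partial_r) arrays."""
    rss = np.maximum(rss_edge, 0.0)
    exact = rss <= _RSS_TOL * max(yr_ss if np.isscalar(yr_ss) else 1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 / ee)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        pvals = 2.0 * sps.t.sf(np.abs(t), df)
        partial = np.sign(t) * np.sqrt(t**2 / (t**2 + df))
    # noiseless fits: se -> 0 limit, p -> 0, |partial r| -> 1
    limit = np.isinf(t) | exact
    partial = np.where(limit, np.sign(beta) * 1.0, partial)
    pvals = np.where(limit, 0.0, pvals)
    return se, t, pvals, partial, exact


def batch_edge_glm(E: np.ndarray, y: np.ndarray, rd: ResidualizedDesign) -> pd.DataFrame:
    """Fit outcome ~ covariates + edge_k for every column of ``E`` at once.

    Parameters
    ----------
    E : ndarray, shape (n, m)
        One column per candidate regressor (edge values, occupancies, ...).
    y : ndarray, shape (n,)
        Outcome.
    rd : ResidualizedDesign
        Prepared from the covariate design matrix (intercept included).

    Returns
    -------
    DataFrame with columns beta, se, t, p, partial_r, df and a boolean
    ``skipped`` flag for regressors that are constant after covariate
    adjustment (their statistics are NaN and they must be excluded from any
    FDR family).
    """
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if E.shape[0] != y.size or E.shape[0] != rd.n:
        raise ValueError("edge matrix, outcome and design have inconsistent row counts")
    yr = rd.residualize(y)
    Er = rd.residualize(E)
    ee = np.einsum("ij,ij->j", Er, Er)
    scale = np.einsum("ij,ij->j", E - E.mean(0), E - E.mean(0))
    skipped = ee <= 1e-12 * np.maximum(scale, 1.0)
    ee_safe = np.where(skipped, 1.0, ee)
    yr_ss = float(yr @ yr)
    beta = (Er.T @ yr) / ee_safe
    df = rd.df_resid
    rss = yr_ss - beta**2 * ee_safe
    se, t, pvals, partial, _ = _finalize(beta, ee_safe, rss, yr_ss, df)
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": t,
            "p": pvals,
            "partial_r": partial,
            "df": df,
            "skipped": skipped,
        }
    )
    out.loc[skipped, ["beta", "se", "t", "p", "partial_r"]] = np.nan
    return out


def fit_edge_glm(edge_values, outcome, design) -> EdgeGLMFit:
    """OLS of ``outcome`` on ``[design | edge_values]``; statistics for the edge term.

    ``design`` must include the intercept (see :func:`edgeproject.io.build_design`).
    Two-sided p from the t distribution with n - rank(design) - 1 degrees of
    freedom.  A constant edge raises (batch callers skip it with a flag).
    """
    e = np.asarray(edge_values, dtype=float).ravel()
    rd = ResidualizedDesign.from_design(design)
    res = batch_edge_glm(e[:, None], np.asarray(outcome, dtype=float), rd)
    row = res.iloc[0]
    if bool(row["skipped"]):
        raise ValueError("edge values are constant after covariate adjustment")
    return EdgeGLMFit(
        beta=float(row.beta),
        se=float(row.se),
        t=float(row.t),
        p=float(row.p),
        partial_r=float(row.partial_r),
        df=int(row.df),
    )


def permutation_t_stats(
    Er_sel: np.ndarray, y: np.ndarray, rd: ResidualizedDesign, perms: np.ndarray
) -> np.ndarray:
    """|t| statistics of selected edges under outcome permutations.

    ``perms`` is an (n_perm, n) array of permutation index rows; the outcome
    vector is shuffled (breaking its link to covariates and edges alike)
    while edges and covariates stay fixed.  Returns (n_perm, m) of t values.
    """
    Yp = y[perms]  # (n_perm, n)
    Ypr = Yp - (Yp @ rd.Q) @ rd.Q.T
    ee = np.einsum("ij,ij->j", Er_sel, Er_sel)
    beta = (Ypr @ Er_sel) / ee
    rss = np.einsum("ij,ij->i", Ypr, Ypr)[:, None] - beta**2 * ee
    rss = np.maximum(rss, 0.0)
    df = rd.df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / ee)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    return t
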