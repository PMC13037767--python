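"""Little's MCAR test from first principles.

The test asks whether the observed-variable means differ across missingness
patterns more than sampling variability under MCAR allows.  Let the wide
table have p variables and let pattern j (n_j rows) observe the subset o_j.
With EM maximum-likelihood estimates (mu, Sigma) of a multivariate normal
under ignorable missingness, the statistic is

    d^2 = sum_j n_j (ybar_j - mu_{o_j})' Sigma_{o_j o_j}^{-1} (ybar_j - mu_{o_j})

which is asymptotically chi-square with df = sum_j p_j - p degrees of
freedom under MCAR (p_j = number of observed variables in pattern j).  Rows
with no observed variables form a zero-dimensional pattern: they contribute
nothing to d^2 or df and are counted but skipped.

The normal model is an approximation for the binary/ordinal covariates that
enter the wide table as numeric scores; this mirrors standard applied use of
the test on mixed-type data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class EMResult(NamedTuple):
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    loglik: np.ndarray  # observed-data log-likelihood per iteration


@dataclass
class LittleResult:
    """Outcome of Little's MCAR test."""

    d2: float
    df: int
    p_value: float
    n_patterns: int
    em_iterations: int
    converged: bool
    n_empty_rows: int = 0
    pattern_sizes: list = field(default_factory=list)

    def __str__(self) -> str:
        p = "NA (df=0)" if self.df == 0 else f"{self.p_value:.4g}"
        return (
            f"Little's MCAR test: d2={self.d2:.2f}, df={self.df}, p={p}, "
            f"{self.n_patterns} patterns"
        )


def _pattern_groups(X: np.ndarray):
    """Group row indices by their observed-variable mask."""
    obs = ~np.isnan(X)
    keys = np.packbits(obs, axis=1)
    order = np.lexsort(keys.T[::-1])
    keys_sorted = keys[order]
    breaks = np.flatnonzero(np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)) + 1
    groups = np.split(order, breaks)
    return [(obs[g[0]], g) for g in groups]


def _solve_spd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive-definite A, with a ridge then
    pseudo-inverse fallback for near-singular pattern submatrices."""
    try:
        np.linalg.cholesky(A)  # SPD check
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * np.trace(A) / A.shape[0]
    try:
        warnings.warn("near-singular covariance submatrix; adding small ridge",
                      RuntimeWarning, stacklevel=3)
        return np.linalg.solve(A + ridge * np.eye(A.shape[0]), B)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance submatrix; using pseudo-inverse",
                      RuntimeWarning, stacklevel=3)
        return np.linalg.pinv(A) @ B


def _observed_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                     groups) -> float:
    """Observed-data normal log-likelihood, pattern by pattern (Cholesky)."""
    ll = 0.0
    for mask, idx in groups:
        if not mask.any():
            continue
        o = np.flatnonzero(mask)
        sub = X[np.ix_(idx, o)] - mu[o]
        S = sigma[np.ix_(o, o)]
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(S + 1e-10 * np.trace(S) / len(o) * np.eye(len(o)))
        z = np.linalg.solve(L, sub.T)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        nj, pj = sub.shape
        ll += -0.5 * (
            nj * (pj * np.log(2.0 * np.pi) + logdet) + (z**2).sum()
        )
    return float(ll)


def em_mvn(
    wide: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """EM maximum-likelihood estimates of a multivariate-normal mean and
    covariance under ignorable missingness.

    Parameters
    ----------
    wide : DataFrame or 2-D array
        One row per unit, NaN for missing cells.  Rows with no observed
        cells contribute nothing and are dropped internally.
    tol : float
        Converged when the max-abs change of all parameters between
        successive iterations falls below ``tol``.
    max_iter : int
        Iteration cap; non-convergence is flagged on the result, not raised.

    Returns
    -------
    EMResult
        ``(mean, cov, n_iter, converged, loglik)``; covariance uses the ML
        divisor n.  The observed-data log-likelihood is non-decreasing
        across iterations (a property the tests check).
    """
    X = np.asarray(wide, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    obs_any = ~np.isnan(X).all(axis=1)
    X = X[obs_any]
    never = np.isnan(X).all(axis=0)
    if never.any():
        raise ValueError(
            f"variable(s) never observed: column index {np.flatnonzero(never).tolist()}"
        )
    n, p = X.shape
    # Work on a per-column standardized scale so the convergence tolerance is
    # scale-free (variables here range from binary covariates to tens of
    # thousands of seconds); estimates are mapped back afterwards and the
    # d2 quadratic form is invariant to this affine rescaling.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(X, axis=0)
        scale = np.nanstd(X, axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    X = (X - center) / scale
    groups = _pattern_groups(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        var = np.nanvar(X, axis=0)
    var = np.where(var > 0, var, 1.0)
    sigma = np.diag(var)

    loglik = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for mask, idx in groups:
            o = np.flatnonzero(mask)
            m = np.flatnonzero(~mask)
            Xo = X[np.ix_(idx, o)]
            nj = len(idx)
            if m.size == 0:
                comp = Xo
                s1 += comp.sum(axis=0)
                s2 += comp.T @ comp
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            # regression of missing on observed: B = Smo Soo^{-1}
            B = _solve_spd(Soo, Smo.T).T
            cond_cov = sigma[np.ix_(m, m)] - B @ Smo.T
            Xm_hat = mu[m] + (Xo - mu[o]) @ B.T
            comp = np.empty((nj, p))
            comp[:, o] = Xo
            comp[:, m] = Xm_hat
            s1 += comp.sum(axis=0)
            s2 += comp.T @ comp
            s2[np.ix_(m, m)] += nj * cond_cov
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        loglik.append(_observed_loglik(X, mu_new, sigma_new, groups))
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    # back to the original scale; the log-likelihood picks up the (constant)
    # Jacobian of the per-column standardization
    obs_counts = (~np.isnan(X)).sum(axis=0)
    jac = -float((obs_counts * np.log(scale)).sum())
    mu_orig = center + scale * mu
    sigma_orig = sigma * np.outer(scale, scale)
    return EMResult(mu_orig, sigma_orig, it, converged, np.asarray(loglik) + jac)


def little_test(
    wide: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LittleResult:
    """Little's chi-square test of the MCAR null hypothesis.

    Complete data (a single all-observed pattern) give a degenerate result
    with d2 = 0, df = 0 and an undefined p-value (a warning, not an error).
    """
    X = np.asarray(wide, dtype=float)
    em = em_mvn(X, tol=tol, max_iter=max_iter)
    mu, sigma = em.mean, em.cov
    p = X.shape[1]

    empty = np.isnan(X).all(axis=1)
    n_empty = int(empty.sum())
    X = X[~empty]
    groups = _pattern_groups(X)

    d2 = 0.0
    df = 0
    sizes = []
    for mask, idx in groups:
        o = np.flatnonzero(mask)
        nj = len(idx)
        sizes.append(nj)
        ybar = X[np.ix_(idx, o)].mean(axis=0)
        diff = ybar - mu[o]
        sol = _solve_spd(sigma[np.ix_(o, o)], diff)
        d2 += nj * float(diff @ sol)
        df += o.size
    df -= p
    n_patterns = len(groups)
    if df <= 0:
        warnings.warn(
            "single missingness pattern (complete data); Little's test is "
            "degenerate with df=0 and an undefined p-value",
            UserWarning,
            stacklevel=2,
        )
        return LittleResult(
            d2=max(d2, 0.0), df=max(df, 0), p_value=float("nan"),
            n_patterns=n_patterns, em_iterations=em.n_iter,
            converged=em.converged, n_empty_rows=n_empty, pattern_sizes=sizes,
        )
    p_value = float(stats.chi2.sf(d2, df))
    if n_empty:
        logger.info(
            "%d all-missing rows formed a zero-dimensional pattern and were skipped",
            n_empty,
        )
    return LittleResult(
        d2=float(d2), df=int(df), p_value=p_value, n_patterns=n_patterns,
        em_iterations=em.n_iter, converged=em.converged,
        n_empty_rows=n_empty, pattern_sizes=sizes,
    )
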