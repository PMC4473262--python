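"""Shared statistical primitives: Benjamini-Hochberg control, Spearman
correlation with t-approximated p-values, and simple OLS with coefficient
tests.

These are deliberately implemented here (rather than delegated wholesale to
statsmodels) because the test suite validates them against independent
brute-force oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_reject(pvalues, fdr: float, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask.

    ``m_total`` overrides the family size, e.g. when the supplied p-values
    are a subset of a larger test family whose remaining members are assumed
    non-rejectable (used for the pre-collapse probe-level family).
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError("m_total smaller than number of p-values")
    order = np.argsort(p, kind="mergesort")
    thresholds = fdr * (np.arange(1, len(p) + 1)) / m
    passing = p[order] <= thresholds
    reject = np.zeros(len(p), dtype=bool)
    if passing.any():
        kmax = np.max(np.nonzero(passing)[0])
        reject[order[: kmax + 1]] = True
    return reject


def bh_cutoff(pvalues, fdr: float, m_total: int | None = None) -> float:
    """Largest p-value rejected by BH (0.0 if nothing is rejected)."""
    p = np.asarray(pvalues, dtype=float)
    reject = bh_reject(p, fdr, m_total)
    return float(p[reject].max()) if reject.any() else 0.0


def bh_qvalues(pvalues, m_total: int | None = None) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p) if m_total is None else int(m_total)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p via the t approximation with n-2 degrees of freedom."""
    if n < 3:
        return 1.0
    r = float(np.clip(rho, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho, two-sided p and n over pairwise-complete samples.

    Average ranks are used for ties (standard Spearman).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    rx = sps.rankdata(x[mask])
    ry = sps.rankdata(y[mask])
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    return rho, spearman_pvalue(rho, n), n


# ---------------------------------------------------------------------------
# OLS with coefficient inference
# ---------------------------------------------------------------------------

def ols_fit(y, X) -> dict:
    """Least-squares fit returning betas, standard errors and two-sided
    p-values for each column of the design matrix ``X``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough observations for OLS")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        se = np.full(k, np.nan)
        p = np.full(k, np.nan)
    else:
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * sps.t.sf(np.abs(t), dof)
    return {"beta": beta, "se": se, "p": p, "resid": resid, "dof": dof}


def covariate_design(covariates: pd.DataFrame, extra: np.ndarray | None = None) -> np.ndarray:
    """Intercept + age + sex design, optionally with one extra predictor
    inserted as the second column (so its coefficient index is 1).
    """
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    cols = [np.ones(len(age))]
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
    cols.extend([age, sex])
    return np.column_stack(cols)
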