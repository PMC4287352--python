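"""Nonparametric association primitives.

Everything downstream of preprocessing is rank-based: Spearman correlation
with average-rank ties and a two-sided p-value from the t approximation
t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.  The scalar
entry point handles missing data (pairwise-complete) and degenerate
inputs; the matrix helpers are the vectorised fast paths used by the
genome-wide scans.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps

MIN_N = 5


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int
    note: str  # "ok", "too-few", "zero-variance"


def spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Spearman rho via the t approximation.

    |rho| = 1 maps to p = 0 exactly.
    """
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    if n < 3:
        return np.ones_like(rho)
    perfect = np.abs(rho) >= 1.0 - 1e-13
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(perfect, 0.0, p)
    return np.minimum(p, 1.0)


def spearman(x, y) -> SpearmanResult:
    """Spearman correlation of two vectors, pairwise-complete.

    Positions where either value is missing are dropped.  Fewer than
    ``MIN_N`` complete pairs, or zero variance in either vector, yield a
    flagged degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < MIN_N:
        return SpearmanResult(float("nan"), 1.0, n, "too-few")
    xr = sps.rankdata(x[mask])
    yr = sps.rankdata(y[mask])
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        return SpearmanResult(0.0, 1.0, n, "zero-variance")
    xr -= xr.mean()
    yr -= yr.mean()
    rho = float(np.dot(xr, yr) / np.sqrt(np.dot(xr, xr) * np.dot(yr, yr)))
    rho = float(np.clip(rho, -1.0, 1.0))
    p = float(spearman_pvalues(np.array([rho]), n)[0])
    return SpearmanResult(rho, p, n, "ok")


def _rank_standardize(X: np.ndarray):
    """Rank each row (average ties), centre and scale to unit norm.

    Returns the standardized matrix and a boolean mask of zero-variance
    rows (which are zeroed so their correlations come out as 0).
    """
    X = np.asarray(X, dtype=float)
    R = sps.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=1))
    flat = norms == 0
    norms[flat] = 1.0
    R /= norms[:, None]
    R[flat] = 0.0
    return R, flat


def spearman_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rho between rows of X and rows of Y.

    X is (p, n), Y is (q, n); the result is (p, q).  Zero-variance rows
    produce rho = 0.
    """
    RX, _ = _rank_standardize(X)
    RY, _ = _rank_standardize(Y)
    return np.clip(RX @ RY.T, -1.0, 1.0)


def spearman_paired(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho between aligned rows of X and Y (same shape)."""
    RX, _ = _rank_standardize(X)
    RY, _ = _rank_standardize(Y)
    return np.clip((RX * RY).sum(axis=1), -1.0, 1.0)


def ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the simple linear regression of y on x (with intercept)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return y - y.mean()
    beta = np.dot(xc, y - y.mean()) / denom
    return y - y.mean() - beta * xc


def spearman_permutation_p(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Brute-force two-sided permutation p-value for Spearman rho.

    Independent oracle for the t approximation: permutes y relative to x
    ``n_perm`` times and counts |rho_perm| >= |rho_obs|, with the +1
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    xr = xr - xr.mean()
    xr /= np.sqrt(np.dot(xr, xr))
    yc = yr - yr.mean()
    yc /= np.sqrt(np.dot(yc, yc))
    obs = abs(float(np.dot(xr, yc)))
    n = len(x)
    # one big (n_perm, n) block of permuted rank vectors
    P = np.tile(yc, (n_perm, 1))
    P = rng.permuted(P, axis=1)
    rhos = P @ xr
    count = int((np.abs(rhos) >= obs - 1e-12).sum())
    return (count + 1) / (n_perm + 1)
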