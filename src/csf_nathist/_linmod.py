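"""Vectorized multi-response ordinary least squares.

Every per-analyte screen in the pipeline fits the *same* design matrix to
thousands of response columns (somamers, pathway scores).  Solving the
normal equations once and broadcasting over responses is orders of
magnitude faster than looping over a general-purpose OLS object, and the
closed-form t / F machinery is exact.  statsmodels serves as the oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class MultiOLSResult:
    """Coefficients and inference for Y (n x m) regressed on X (n x k).

    Attributes are all shaped (k, m) except where noted; column j holds the
    fit of response j.
    """

    coef: np.ndarray        # (k, m)
    se: np.ndarray          # (k, m)
    t: np.ndarray           # (k, m)
    p: np.ndarray           # (k, m) two-sided coefficient p-values
    r2: np.ndarray          # (m,)
    f_stat: np.ndarray      # (m,) whole-model F (against intercept-only)
    f_p: np.ndarray         # (m,) whole-model p
    sigma2: np.ndarray      # (m,) residual variance (df = n - k)
    df_resid: int
    fitted: np.ndarray      # (n, m)
    resid: np.ndarray       # (n, m)


def multi_ols(X: np.ndarray, Y: np.ndarray) -> MultiOLSResult:
    """Fit Y[:, j] ~ X for every column j in one shot.

    X must include an intercept column if one is wanted; the whole-model F
    test assumes the first column of X is the intercept.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (X.T @ Y)
    fitted = X @ coef
    resid = Y - fitted
    df_resid = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df_resid
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    df_model = k - 1
    if df_model > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = np.where(rss > 0, (tss - rss) / df_model / sigma2, np.inf)
        f_p = stats.f.sf(f_stat, df_model, df_resid)
    else:
        f_stat = np.zeros_like(r2)
        f_p = np.ones_like(r2)
    return MultiOLSResult(coef=coef, se=se, t=t, p=p, r2=r2, f_stat=f_stat,
                          f_p=f_p, sigma2=sigma2, df_resid=df_resid,
                          fitted=fitted, resid=resid)


def simple_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of y ~ x for a single series (exact two-point safe)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate regressor (no variation)")
    slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xm)
    return slope, intercept
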