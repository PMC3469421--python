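"""Vectorized simple linear regression used throughout the pipeline.

Every association in the pipeline is a one-predictor OLS fit (abundance on
time, expression on decay, phenotype on dosage), so a single closed-form
routine serves all of them: slope, intercept, slope standard error and a
two-sided t-test on the slope with n - 2 degrees of freedom.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["SlopeFit", "ols_slope"]

# Residual sums below this (relative to total SS) are treated as exact fits.
_EXACT_FIT_RTOL = 1e-12


class SlopeFit(NamedTuple):
    """Closed-form OLS results; all arrays broadcast over the leading axes."""

    slope: np.ndarray
    intercept: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    exact_fit: np.ndarray


def ols_slope(x: np.ndarray, y: np.ndarray) -> SlopeFit:
    """Regress ``y`` on ``x`` along the last axis.

    Parameters
    ----------
    x
        Predictor, 1-D of length n (shared design) or broadcastable to ``y``.
    y
        Response array ``(..., n)``.

    Returns
    -------
    SlopeFit
        Element-wise results with shape ``y.shape[:-1]``.  For exact fits
        (zero residual variance) ``se`` is 0 and ``p`` is 0 when the slope is
        nonzero, 1 when the fitted line is flat.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 observations for a slope t-test")
    if x.shape[-1] != n:
        raise ValueError("x and y disagree on the number of observations")

    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = np.sum(xc * xc, axis=-1)
    if np.any(sxx <= 0):
        raise ValueError("predictor is constant; slope undefined")
    sxy = np.sum(xc * yc, axis=-1)
    syy = np.sum(yc * yc, axis=-1)

    slope = sxy / sxx
    intercept = y.mean(axis=-1) - slope * x.mean(axis=-1)
    rss = syy - slope * sxy
    rss = np.maximum(rss, 0.0)

    exact = rss <= _EXACT_FIT_RTOL * np.maximum(syy, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
        tval = slope / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)

    # Exact fits: the t statistic degenerates; report certainty about the sign.
    if np.ndim(slope) == 0:
        if exact:
            se = np.float64(0.0)
            p = np.float64(1.0 if slope == 0 else 0.0)
            tval = np.float64(0.0 if slope == 0 else np.inf * np.sign(slope))
    else:
        se = np.where(exact, 0.0, se)
        p = np.where(exact, np.where(slope == 0, 1.0, 0.0), p)
        t_exact = np.where(slope == 0, 0.0, np.where(slope > 0, np.inf, -np.inf))
        tval = np.where(exact, t_exact, tval)
    return SlopeFit(slope, intercept, se, tval, p, exact)
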