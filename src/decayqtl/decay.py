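"""Relative mRNA decay-rate estimation from transcription-arrest time courses.

With equal RNA mass hybridized at every harvest, the log2 intensity of gene g
in individual i follows a first-order model whose slope is the decay rate
*relative* to the mean cellular rate:

    y(t) = B0 - k * t + eps,     eps ~ N(0, sigma^2)

k > 0 means faster-than-average decay, k = 0 decay at exactly the cell-wide
mean.  Each gene x individual series is fit by OLS; the per-fit two-sided
t-test (n_timepoints - 2 df) drives the consistently-fast/slow classification.
The mean cellular rate itself is recovered from the study design (cells
harvested and total RNA yield per time point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import ols_slope
from .containers import DecayMatrix, ExpressionCube, MeanCellularRate

__all__ = [
    "DecayEstimate",
    "DecayClass",
    "fit_decay_rate",
    "fit_decay_matrix",
    "estimate_mean_cellular_rate",
    "to_absolute_rates",
    "classify_decay_genes",
    "feature_rank_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class DecayEstimate:
    """One gene x individual fit: relative rate, its SE, t-test p, intercept."""

    k: float
    se: float
    p: float
    b0: float
    exact_fit: bool = False


def fit_decay_rate(log2_values, time_points_h) -> DecayEstimate:
    """OLS fit of one log2 abundance series on time; k = -slope.

    Requires at least 3 time points.  A zero-residual series is flagged as an
    exact fit with se = 0 and p = 0 (p = 1 for a perfectly flat line, which
    carries no evidence against k = 0).
    """
    y = np.asarray(log2_values, dtype=float)
    t = np.asarray(time_points_h, dtype=float)
    if y.ndim != 1 or t.shape != y.shape:
        raise ValueError("log2_values and time_points_h must be matched 1-D vectors")
    if len(t) < 3:
        raise ValueError("need at least 3 time points to fit a decay rate")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values in decay fit input")
    fit = ols_slope(t, y)
    return DecayEstimate(
        k=float(-fit.slope),
        se=float(fit.se),
        p=float(fit.p),
        b0=float(fit.intercept),
        exact_fit=bool(fit.exact_fit),
    )


def fit_decay_matrix(cube: ExpressionCube) -> DecayMatrix:
    """Fit every gene x individual decay rate in one vectorized pass."""
    if cube.feature_level != "gene":
        raise ValueError("decay fitting expects a gene-level cube")
    t = cube.time_points_h
    fit = ols_slope(t, cube.values)  # leading axes: gene x individual
    bad = ~np.isfinite(fit.slope)
    if bad.any():
        logger.warning("%d decay fits failed (non-finite)", int(bad.sum()))
    genes = pd.Index(cube.features, name="gene_id")
    inds = pd.Index(cube.individuals, name="individual_id")

    def frame(arr):
        return pd.DataFrame(np.asarray(arr, dtype=float), index=genes, columns=inds)

    return DecayMatrix(
        k=frame(-fit.slope),
        se=frame(fit.se),
        p=frame(fit.p),
        b0=frame(fit.intercept),
        exact_fit=frame(fit.exact_fit),
    )


def estimate_mean_cellular_rate(
    cells_per_timepoint,
    rna_yields,
    time_points_h,
    scope: str = "global",
) -> MeanCellularRate:
    """Mean cellular decay rate from the harvest design.

    Per-cell RNA mass is yield / cells; its log2 decline over time is the
    rate at which the whole transcript pool decays, i.e. the k = 0 reference
    of the relative-rate scale.
    """
    cells = np.asarray(cells_per_timepoint, dtype=float)
    yields = np.asarray(rna_yields, dtype=float)
    t = np.asarray(time_points_h, dtype=float)
    if cells.shape != t.shape or yields.shape != t.shape:
        raise ValueError("cells, yields and time points must be matched vectors")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(cells <= 0) or np.any(yields <= 0):
        raise ValueError("cell counts and RNA yields must be positive")
    per_cell = yields / cells
    fit = ols_slope(t, np.log2(per_cell))
    return MeanCellularRate(lambda_bar=float(-fit.slope), se=float(fit.se), scope=scope)


def to_absolute_rates(
    decay: DecayMatrix, mean_rate: MeanCellularRate
) -> Tuple[DecayMatrix, pd.DataFrame]:
    """Shift relative rates onto the absolute scale: k_abs = k + lambda_bar.

    Returns the shifted matrix and a gene x individual half-life table
    (1 / k_abs hours); entries with k_abs <= 0 — transcripts decaying slower
    than measurable under the equal-mass normalization — get NaN half-lives.
    """
    if mean_rate.per_individual is not None:
        shift = mean_rate.per_individual.reindex(decay.individuals)
        if shift.isna().any():
            raise ValueError("per-individual mean rates do not cover all individuals")
        k_abs = decay.k.add(shift, axis=1)
    else:
        k_abs = decay.k + mean_rate.lambda_bar
    half_life = 1.0 / k_abs.where(k_abs > 0)
    shifted = DecayMatrix(
        k=k_abs, se=decay.se.copy(), p=decay.p.copy(), b0=decay.b0.copy(),
        exact_fit=None if decay.exact_fit is None else decay.exact_fit.copy(),
    )
    return shifted, half_life


@dataclass
class DecayClass:
    """Per-gene consistently-fast/slow labels with supporting counts."""

    labels: pd.Series  # gene_id -> "fast" | "slow" | "neither"
    counts: pd.DataFrame  # n_sig_fast, n_sig_slow, n_individuals

    def genes(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def classify_decay_genes(
    decay: DecayMatrix, alpha: float = 0.1, min_frac: float = 0.8
) -> DecayClass:
    """Label genes decaying consistently faster or slower than the mean rate.

    A gene is "fast" when at least ``min_frac`` of individuals (with
    non-missing fits) have k > 0 at p < ``alpha``; "slow" symmetrically for
    k < 0; otherwise "neither".  Genes with no usable fits are "neither".
    """
    k = decay.k.to_numpy()
    p = decay.p.to_numpy()
    ok = np.isfinite(k) & np.isfinite(p)
    n_ok = ok.sum(axis=1)
    sig = ok & (p < alpha)
    n_fast = (sig & (k > 0)).sum(axis=1)
    n_slow = (sig & (k < 0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_fast = np.where(n_ok > 0, n_fast / np.maximum(n_ok, 1), 0.0)
        frac_slow = np.where(n_ok > 0, n_slow / np.maximum(n_ok, 1), 0.0)
    labels = np.where(
        frac_fast >= min_frac, "fast", np.where(frac_slow >= min_frac, "slow", "neither")
    )
    all_missing = n_ok == 0
    if all_missing.any():
        logger.warning("%d genes have no usable decay fits", int(all_missing.sum()))
        labels = np.where(all_missing, "neither", labels)
    genes = decay.genes
    return DecayClass(
        labels=pd.Series(labels, index=genes, name="decay_class"),
        counts=pd.DataFrame(
            {"n_sig_fast": n_fast, "n_sig_slow": n_slow, "n_individuals": n_ok},
            index=genes,
        ),
    )


def feature_rank_correlation(
    per_gene_feature: pd.Series,
    per_gene_median_k: pd.Series,
    subset: Optional[pd.Index] = None,
) -> Tuple[float, float]:
    """Spearman rank correlation between a gene feature (e.g. gene length or
    3'UTR length) and the per-gene median decay rate.

    Optionally restricted to a gene subset (e.g. the consistently fast/slow
    genes).  Returns (rho, two-sided p, t approximation).
    """
    joined = pd.concat(
        [per_gene_feature.rename("feature"), per_gene_median_k.rename("k")], axis=1
    ).dropna()
    if subset is not None:
        joined = joined.loc[joined.index.intersection(subset)]
    if len(joined) < 4:
        raise ValueError("need at least 4 paired non-missing values")
    if joined["feature"].nunique() < 2 or joined["k"].nunique() < 2:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(joined["feature"], joined["k"])
    return float(res.statistic), float(res.pvalue)
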