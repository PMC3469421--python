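"""Sharing between QTL classes: Storey pi0 with bootstrap lambda selection,
the min-p order-statistic transform, and closed-form overlap arithmetic.

pi0 estimates the fraction of tests generated under the null; 1 - pi0 is the
power-corrected estimate of the fraction of true associations, the quantity
used to say "X% of eQTLs are also associated with decay" without conditioning
on per-test significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "Pi0Estimate",
    "pi0_storey_bootstrap",
    "min_p_transform",
    "expected_overlap",
    "overlap_significance",
    "union_fraction",
]


@dataclass
class Pi0Estimate:
    """Storey pi0 with the bootstrap lambda choice of Storey & Tibshirani (2003)."""

    lambda_grid: np.ndarray
    pi0_at_lambda: np.ndarray
    selected_lambda: float
    pi0_hat: float
    bootstrap_ci: Tuple[float, float]
    n_bootstrap: int


def pi0_storey_bootstrap(
    p_values,
    lambda_grid=None,
    n_bootstrap: int = 100,
    seed=0,
) -> Pi0Estimate:
    """Estimate the null fraction pi0 from a p-value distribution.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid of lambda;
    lambda is chosen to minimize the bootstrap mean squared error against a
    robust lower target — the 0.1 quantile of pi0(lambda) over the grid, as
    in the released qvalue software (targeting the plain minimum biases pi0
    downward under a full null) — and the estimate is clipped to [0, 1].
    A percentile bootstrap CI at the selected lambda is reported.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 50:
        raise ValueError("need at least 50 p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = (
        np.arange(0.0, 0.96, 0.05) if lambda_grid is None
        else np.asarray(lambda_grid, dtype=float)
    )
    if np.any((grid < 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")
    m = p.size

    def pi0_of(sample: np.ndarray) -> np.ndarray:
        exceed = (sample[None, :] > grid[:, None]).sum(axis=1)
        return exceed / (sample.size * (1.0 - grid))

    pi0_lam = pi0_of(p)
    min_pi0 = max(float(np.quantile(pi0_lam, 0.1)), 0.0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, grid.size))
    for b in range(n_bootstrap):
        boot[b] = pi0_of(rng.choice(p, size=m, replace=True))
    mse = np.mean((boot - min_pi0) ** 2, axis=0)
    best = int(np.argmin(mse))
    pi0_hat = float(np.clip(pi0_lam[best], 0.0, 1.0))
    ci = np.percentile(np.clip(boot[:, best], 0.0, 1.0), [2.5, 97.5])
    return Pi0Estimate(
        lambda_grid=grid,
        pi0_at_lambda=pi0_lam,
        selected_lambda=float(grid[best]),
        pi0_hat=pi0_hat,
        bootstrap_ci=(float(ci[0]), float(ci[1])),
        n_bootstrap=n_bootstrap,
    )


def min_p_transform(p_a, p_b):
    """Order-statistic transform of the smaller of two p-values.

    For two independent uniform null p-values, min(p_a, p_b) has CDF
    1 - (1 - x)^2; applying that CDF returns the combined statistic to the
    uniform scale.  NOTE: this closed form is this package's reconstruction
    of the minimum-p calibration — it is the unique monotone transform that
    makes the two-phenotype minimum uniform under the joint null.
    """
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mn = np.minimum(a, b)
    out = 1.0 - (1.0 - mn) ** 2
    return out if out.ndim else float(out)


def expected_overlap(n_a: int, n_b: int, n_total: int) -> Tuple[float, int]:
    """Chance overlap of two subsets drawn from ``n_total`` items:
    the hypergeometric expectation n_a * n_b / n_total, plus its nearest
    integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_a > n_total or n_b > n_total or min(n_a, n_b) < 0:
        raise ValueError("subset sizes must lie in [0, n_total]")
    expectation = n_a * n_b / n_total
    return expectation, int(round(expectation))


def overlap_significance(n_a: int, n_b: int, n_overlap: int, n_total: int) -> float:
    """Upper hypergeometric tail P(X >= n_overlap) for the observed overlap."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    return float(stats.hypergeom.sf(n_overlap - 1, n_total, n_a, n_b))


def union_fraction(n_a: int, n_b: int, n_overlap: int, n_total: int) -> float:
    """Percent of ``n_total`` covered by the union of two sets, to one decimal.

    E.g. the share of eQTLs that are also rdQTLs and/or dsQTLs.
    """
    if n_overlap > min(n_a, n_b) or min(n_a, n_b, n_overlap) < 0:
        raise ValueError("inconsistent counts")
    union = n_a + n_b - n_overlap
    if union > n_total or n_total <= 0:
        raise ValueError("inconsistent counts")
    return round(100.0 * union / n_total, 1)
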