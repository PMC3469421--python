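"""Decay-versus-expression association across individuals, permutation FDR,
and tail-overlap analysis.

For each gene, steady-state expression y_i is regressed on the decay rate
r_i across individuals:

    y_i = mu + beta * r_i + eps_i

A negative t statistic is the kinetically intuitive ("concordant")
direction — faster decay, lower expression; a positive t is "discordant".
Significance is calibrated against an empirical null built by re-running the
analysis on label-permuted decay matrices: permutations reshuffle individual
labels consistently across genes (preserving the gene-gene correlation of
decay) and the permuted p-values are pooled into one null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._regression import ols_slope

__all__ = [
    "GeneAssociationTable",
    "FdrTable",
    "decay_expression_association",
    "permute_decay_matrix",
    "permutation_fdr",
    "tail_overlap",
]


@dataclass
class GeneAssociationTable:
    """Per-gene results of the expression-on-decay regression."""

    table: pd.DataFrame  # gene_id index; beta, t, p, direction

    def __post_init__(self) -> None:
        need = {"beta", "t", "p", "direction"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"association table must have columns {sorted(need)}")

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


def decay_expression_association(
    steady_state: pd.DataFrame, decay: pd.DataFrame
) -> GeneAssociationTable:
    """Regress steady-state expression on decay rate, gene by gene.

    Both inputs are gene x individual matrices on identical grids.  Genes
    whose decay vector is constant are returned with NaN statistics and
    direction "undefined".
    """
    if not steady_state.index.equals(decay.index) or not steady_state.columns.equals(
        decay.columns
    ):
        raise ValueError("steady_state and decay must share gene and individual axes")
    if steady_state.shape[1] < 4:
        raise ValueError("need at least 4 individuals")
    y = steady_state.to_numpy(dtype=float)
    r = decay.to_numpy(dtype=float)

    const = np.nanstd(r, axis=1) == 0
    beta = np.full(len(y), np.nan)
    tval = np.full(len(y), np.nan)
    pval = np.full(len(y), np.nan)
    good = ~const
    if good.any():
        # per-gene predictor differs, so ols_slope is called with matched rows
        fit = ols_slope(r[good], y[good])
        beta[good], tval[good], pval[good] = fit.slope, fit.t, fit.p
    direction = np.where(
        np.isnan(tval), "undefined", np.where(tval < 0, "concordant", "discordant")
    )
    table = pd.DataFrame(
        {"beta": beta, "t": tval, "p": pval, "direction": direction},
        index=steady_state.index,
    )
    return GeneAssociationTable(table)


def permute_decay_matrix(
    decay: pd.DataFrame, n_perms: int, seed
) -> list[pd.DataFrame]:
    """Permuted decay matrices: individual labels reshuffled, consistently
    across genes within each permutation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    n = decay.shape[1]
    for _ in range(n_perms):
        idx = rng.permutation(n)
        out.append(pd.DataFrame(decay.to_numpy()[:, idx], index=decay.index,
                                columns=decay.columns))
    return out


@dataclass
class FdrTable:
    """Per-gene q-values against a pooled permutation null."""

    q: pd.Series
    threshold_p: float  # largest observed p achieving the target FDR (NaN if none)
    target_fdr: float
    n_significant: int

    def significant(self) -> pd.Index:
        return self.q.index[self.q <= self.target_fdr]


def permutation_fdr(
    observed_p: pd.Series,
    null_p: Sequence[float],
    n_perms: int,
    target_fdr: float = 0.10,
) -> FdrTable:
    """Empirical FDR from a pooled permutation null.

    At threshold t, FDR(t) = (#{null p <= t} / n_perms) / max(1, #{observed
    p <= t}); the per-gene q-value is the minimum FDR over thresholds at or
    beyond that gene's p, clipped to [0, 1] (which also enforces
    monotonicity of q in p).  Genes with missing p get q = NaN.
    """
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    null = np.sort(np.asarray(null_p, dtype=float))
    if null.size == 0:
        raise ValueError("empty permutation null")
    obs = observed_p.to_numpy(dtype=float)
    ok = np.isfinite(obs)
    q = np.full(obs.shape, np.nan)

    p_ok = obs[ok]
    order = np.argsort(p_ok, kind="stable")
    sorted_p = p_ok[order]
    n_null_le = np.searchsorted(null, sorted_p, side="right")
    n_obs_le = np.arange(1, len(sorted_p) + 1)
    fdr = (n_null_le / n_perms) / np.maximum(1, n_obs_le)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q_ok = np.empty_like(q_sorted)
    q_ok[order] = q_sorted
    q[ok] = q_ok

    sig = q_sorted <= target_fdr
    threshold_p = float(sorted_p[sig].max()) if sig.any() else float("nan")
    q_series = pd.Series(q, index=observed_p.index, name="q")
    return FdrTable(
        q=q_series,
        threshold_p=threshold_p,
        target_fdr=target_fdr,
        n_significant=int(np.nansum(q <= target_fdr)),
    )


def tail_overlap(
    median_decay: pd.Series, median_expression: pd.Series, q: float
) -> pd.Index:
    """Genes in the top ``q`` tail of BOTH the decay-rate and steady-state
    expression distributions (the fast-decay / high-expression discordant set).

    Tail membership is strict: values greater than the nearest-rank (1 - q)
    quantile.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    joined = pd.concat(
        [median_decay.rename("k"), median_expression.rename("y")], axis=1
    ).dropna()

    def top(values: pd.Series) -> pd.Index:
        v = values.to_numpy()
        n = len(v)
        # nearest-rank (1 - q) quantile; keep strictly greater values
        rank = max(1, int(np.ceil((1.0 - q) * n)))
        cut = np.sort(v)[rank - 1]
        return values.index[v > cut]

    return top(joined["k"]).intersection(top(joined["y"]))
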