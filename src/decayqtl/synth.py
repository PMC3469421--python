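"""Synthetic transcription-arrest studies with planted decay and expression QTLs.

The generator emulates the design of an actinomycin-D time-course experiment
in a panel of lymphoblastoid cell lines: per-cell first-order mRNA decay,
harvests at a fixed grid of post-arrest times with increasing cell numbers,
and equal-mass hybridization, which makes measured decay rates *relative* to
the mean cellular decay rate (a transcript decaying at exactly the cell-wide
average traces a flat log2 profile).

Kinetic model
-------------
Per cell, gene g in individual i holds ``m_gi(t) = m_gi(0) * 2^(-k_abs_gi t)``
with absolute rate ``k_abs`` in log2-units/hour (half-life = 1/k_abs hours).
Steady state before arrest obeys ``m(0) = T / k_abs`` (synthesis over decay),
so a variant that speeds decay automatically lowers baseline expression — the
kinetically *concordant* direction.  A coupled transcription effect (tuned by
``coupling_rho``) can override this and produce discordant genes.

Equal-mass measurement: the array sees ``log2 m_gi(t) - log2 M_i(t)`` up to a
constant, where ``M_i(t)`` is the per-cell transcript pool.  In ``"exact"``
mode the pool term is imposed as ``-lambda_bar * t`` (clean identities for
testing); in ``"pool"`` mode it is computed from the simulated pool itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionCube, GenotypeMatrix, validate_annotations

__all__ = [
    "SimConfig",
    "TrueParameters",
    "SimulatedStudy",
    "simulate_study",
    "simulate_genotypes",
]

_LN2 = math.log(2.0)


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for :func:`simulate_study`.

    Defaults follow the emulated study: five harvests at 0/0.5/1/2/4 h with
    cell numbers growing to offset pool decay, Gaussian log2 array noise of
    0.2 (the array noise level is not pinned down by the design, so this is a
    package choice, exposed here), and a mean cellular decay rate of 0.3
    log2-units/h (pool half-life ~3.3 h, typical of mammalian cells).
    """

    n_genes: int = 200
    n_individuals: int = 50
    time_points_h: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0)
    cells_per_timepoint: Optional[Sequence[int]] = None
    noise_sd_log2: float = 0.2
    frac_rdqtl: float = 0.1
    frac_eqtl_baseline: float = 0.1
    decay_effect_a: float = 0.2
    baseline_effect_log2: float = 0.5
    coupling_rho: float = 0.0
    maf_range: Tuple[float, float] = (0.1, 0.5)
    variants_per_gene_window: int = 5
    mean_rate_mode: str = "exact"
    lambda_bar: float = 0.3
    sd_log2_k_gene: float = 0.6
    sd_log2_k_individual: float = 0.1
    mean_log2_baseline: float = 8.0
    sd_log2_transcription_gene: float = 1.0
    sd_log2_transcription_individual: float = 0.2
    rna_pg_per_cell_t0: float = 20.0
    gene_length_bp: int = 20_000
    gene_spacing_bp: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points_h, dtype=float)
        if len(tp) < 3:
            raise ValueError("need at least 3 time points")
        if tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time points must start at 0 and strictly increase")
        for name in ("frac_rdqtl", "frac_eqtl_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_rdqtl + self.frac_eqtl_baseline > 1.0:
            raise ValueError("QTL fractions must sum to at most 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.mean_rate_mode not in ("exact", "pool"):
            raise ValueError("mean_rate_mode must be 'exact' or 'pool'")
        if self.variants_per_gene_window < 1:
            raise ValueError("need at least one variant per cis window")
        if self.lambda_bar <= 0:
            raise ValueError("lambda_bar must be positive")
        if self.cells_per_timepoint is not None:
            cells = np.asarray(self.cells_per_timepoint)
            if len(cells) != len(tp):
                raise ValueError("cells_per_timepoint length must match time points")
            if np.any(cells <= 0) or np.any(np.diff(cells) < 0):
                raise ValueError("cell counts must be positive and non-decreasing")

    def resolved_cells(self) -> np.ndarray:
        """Cell counts per time point; default grows as 2^(lambda_bar * t)."""
        if self.cells_per_timepoint is not None:
            return np.asarray(self.cells_per_timepoint, dtype=int)
        tp = np.asarray(self.time_points_h, dtype=float)
        return np.ceil(1e6 * 2.0 ** (self.lambda_bar * tp)).astype(int)


@dataclass
class TrueParameters:
    """Ground truth of a simulated study.

    ``k_abs`` and ``baseline_log2_m0`` are gene x individual DataFrames;
    ``lambda_bar`` is the per-individual mean cellular rate; ``qtl_table``
    lists each planted variant with its decay effect (log2-units/h per minor
    allele) and its direct transcription effect (log2 units per minor allele).
    """

    k_abs: pd.DataFrame
    lambda_bar: pd.Series
    baseline_log2_m0: pd.DataFrame
    qtl_table: pd.DataFrame

    @property
    def k_relative(self) -> pd.DataFrame:
        """Planted relative rates k_abs - lambda_bar (what the estimator sees)."""
        return self.k_abs.sub(self.lambda_bar, axis=1)


@dataclass
class SimulatedStudy:
    """All inputs a real study would provide, plus the detection mask."""

    cube: ExpressionCube
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    design: pd.DataFrame  # individual_id, time_h, cells, rna_yield_ng


def simulate_genotypes(
    n_variants: int,
    n_individuals: int,
    maf_range: Tuple[float, float],
    seed,
    positions: Optional[np.ndarray] = None,
    chrom: str = "chr1",
    id_prefix: str = "rs",
) -> GenotypeMatrix:
    """Independent biallelic variants with Binomial(2, f) dosages.

    ``f`` is drawn uniformly from ``maf_range`` per variant; draws that come
    out monomorphic in the cohort are redrawn (a monomorphic variant carries
    no association information and is rejected at simulation level).  ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = np.empty((n_variants, n_individuals), dtype=np.int8)
    for v in range(n_variants):
        for _ in range(1000):
            f = rng.uniform(lo, hi)
            d = rng.binomial(2, f, size=n_individuals)
            if d.min() != d.max():
                # code the cohort minor allele (ties at 0.5 keep the draw)
                if d.mean() > 1.0:
                    d = 2 - d
                dosages[v] = d
                break
        else:  # pragma: no cover - requires pathological maf/n
            raise RuntimeError("could not draw a polymorphic variant")
    if positions is None:
        positions = 1000 * (1 + np.arange(n_variants))
    variants = pd.DataFrame(
        {
            "variant_id": [f"{id_prefix}{v + 1}" for v in range(n_variants)],
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "G",
        }
    )
    individuals = np.array([f"IND{i + 1:03d}" for i in range(n_individuals)], dtype=object)
    return GenotypeMatrix(dosages=dosages, variants=variants, individuals=individuals)


def _gene_annotations(config: SimConfig) -> pd.DataFrame:
    starts = 100_000 + config.gene_spacing_bp * np.arange(config.n_genes)
    return validate_annotations(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + config.gene_length_bp,
                "strand": "+",
                "gene_id": [f"G{g + 1:04d}" for g in range(config.n_genes)],
            }
        )
    )


def simulate_study(config: SimConfig) -> Tuple[SimulatedStudy, TrueParameters]:
    """Generate a complete study (expression cube, genotypes, annotations,
    design) together with its ground truth.

    The measured log2 intensity is::

        y_git = baseline_log2_m0_gi - (k_abs_gi - lambda_bar_i) * t + eps

    in ``"exact"`` mode; in ``"pool"`` mode the ``lambda_bar * t`` term is
    replaced by the actual log2 decline of the simulated per-cell pool.
    Planted decay QTLs shift ``k_abs`` by ``decay_effect_a`` per minor allele;
    baselines follow the steady-state relation baseline = transcription /
    k_abs, so a pure decay QTL induces a concordant expression effect, while
    ``coupling_rho`` plants a proportional transcription effect that pushes
    joint QTLs toward discordance.
    """
    root = np.random.SeedSequence(config.seed)
    s_geno, s_truth, s_noise = root.spawn(3)
    rng_truth = np.random.default_rng(s_truth)
    rng_noise = np.random.default_rng(s_noise)
    rng_geno = np.random.default_rng(s_geno)

    G, N = config.n_genes, config.n_individuals
    tp = np.asarray(config.time_points_h, dtype=float)
    T = len(tp)
    annotations = _gene_annotations(config)
    genes = annotations["gene_id"].to_numpy()
    individuals = np.array([f"IND{i + 1:03d}" for i in range(N)], dtype=object)

    # --- genotypes: variants_per_gene_window variants inside each cis window
    window = 25_000
    pos_list: List[np.ndarray] = []
    for g in range(G):
        lo = max(1, int(annotations.loc[g, "start"]) + 1 - window)
        hi = int(annotations.loc[g, "end"]) + window
        pos = np.sort(
            rng_geno.choice(
                np.arange(lo, hi + 1), size=config.variants_per_gene_window, replace=False
            )
        )
        pos_list.append(pos)
    all_pos = np.concatenate(pos_list)
    genotypes = simulate_genotypes(
        n_variants=G * config.variants_per_gene_window,
        n_individuals=N,
        maf_range=config.maf_range,
        seed=rng_geno,
        positions=all_pos,
        chrom="chr1",
    )
    genotypes.individuals = individuals
    var_gene = np.repeat(np.arange(G), config.variants_per_gene_window)

    # --- planted QTLs: disjoint rdQTL and baseline-eQTL gene sets
    n_rd = int(round(config.frac_rdqtl * G))
    n_eq = int(round(config.frac_eqtl_baseline * G))
    chosen = rng_truth.choice(G, size=n_rd + n_eq, replace=False)
    rd_genes, eq_genes = chosen[:n_rd], chosen[n_rd:]

    decay_eff = np.zeros(G)
    trans_eff = np.zeros(G)
    causal_variant = np.full(G, -1)

    signs = rng_truth.choice([-1.0, 1.0], size=n_rd)
    # log2-expression units induced per unit of decay effect near lambda_bar;
    # coupling_rho scales a transcription effect twice that size, so rho
    # beyond ~0.5 flips the net expression effect to the discordant side.
    coupling_scale = 2.0 / (config.lambda_bar * _LN2)
    for j, g in enumerate(rd_genes):
        decay_eff[g] = config.decay_effect_a * signs[j]
        trans_eff[g] = config.coupling_rho * coupling_scale * decay_eff[g]
    eq_signs = rng_truth.choice([-1.0, 1.0], size=n_eq)
    for j, g in enumerate(eq_genes):
        trans_eff[g] = config.baseline_effect_log2 * eq_signs[j]
    for g in np.concatenate([rd_genes, eq_genes]).astype(int):
        first = g * config.variants_per_gene_window
        causal_variant[g] = first + rng_truth.integers(config.variants_per_gene_window)

    dos = genotypes.dosages.astype(float)  # (V, N)

    # --- true kinetic parameters: positive rates, log-normal around lambda_bar
    g_gene = rng_truth.normal(0.0, config.sd_log2_k_gene, size=G)
    g_ind = rng_truth.normal(0.0, config.sd_log2_k_individual, size=(G, N))
    k_gene = config.lambda_bar * 2.0 ** g_gene
    # genes carrying a negative planted effect need baseline headroom so the
    # additive per-allele shift cannot push any individual's rate to zero;
    # the 2^(5 sd) margin covers individual-level rate variation to 5 sigma
    neg = decay_eff < 0
    margin = 2.0 ** (5.0 * config.sd_log2_k_individual)
    k_gene[neg] = np.maximum(
        k_gene[neg], 2.0 * np.abs(decay_eff[neg]) * margin + 0.05
    )
    k_abs = k_gene[:, None] * 2.0 ** g_ind
    t_gene = rng_truth.normal(config.mean_log2_baseline, config.sd_log2_transcription_gene, size=G)
    t_ind = rng_truth.normal(0.0, config.sd_log2_transcription_individual, size=(G, N))
    log2_T = t_gene[:, None] + t_ind
    for g in range(G):
        v = causal_variant[g]
        if v >= 0:
            k_abs[g] += decay_eff[g] * dos[v]
            log2_T[g] += trans_eff[g] * dos[v]
    if np.any(k_abs <= 0):
        raise ValueError(
            "planted effects drive some absolute decay rates non-positive; "
            f"min k_abs = {k_abs.min():.4f} (reduce decay_effect_a or sd_k_*)"
        )
    baseline = log2_T - np.log2(k_abs)  # log2 steady-state per-cell abundance

    lambda_bar_i = np.full(N, config.lambda_bar)
    if config.mean_rate_mode == "pool":
        # per-cell pool mass over time, per individual
        m0 = 2.0 ** baseline  # (G, N)
        pool = m0[:, :, None] * 2.0 ** (-k_abs[:, :, None] * tp[None, None, :])
        M = pool.sum(axis=0)  # (N, T)
        pool_term = np.log2(M / M[:, [0]])  # (N, T), 0 at t=0
        # emergent mean cellular rate: OLS slope of log2 pool mass on time
        tc = tp - tp.mean()
        lambda_bar_i = -(pool_term @ tc) / np.sum(tc * tc)
        # measured = per-cell abundance minus pool mass (equal-mass hybridization)
        y = baseline[:, :, None] - k_abs[:, :, None] * tp[None, None, :] - pool_term[None, :, :]
        per_cell_mass = config.rna_pg_per_cell_t0 * (M / M[:, [0]])  # (N, T) in pg
    else:
        k_rel = k_abs - lambda_bar_i[None, :]
        y = baseline[:, :, None] - k_rel[:, :, None] * tp[None, None, :]
        per_cell_mass = config.rna_pg_per_cell_t0 * 2.0 ** (
            -np.outer(lambda_bar_i, tp)
        )  # (N, T)

    if config.noise_sd_log2 > 0:
        y = y + rng_noise.normal(0.0, config.noise_sd_log2, size=y.shape)

    detection = y > 3.0  # well above array background for the default baseline scale

    cube = ExpressionCube(
        values=y,
        features=genes,
        individuals=individuals,
        time_points_h=tp,
        feature_level="gene",
        detection=detection,
    )

    cells = config.resolved_cells()
    design = pd.DataFrame(
        {
            "individual_id": np.repeat(individuals, T),
            "time_h": np.tile(tp, N),
            "cells": np.tile(cells, N),
            "rna_yield_ng": (np.tile(cells, N) * per_cell_mass.ravel()) / 1000.0,
        }
    )

    qtl_rows = []
    for g in range(G):
        if causal_variant[g] >= 0:
            qtl_rows.append(
                {
                    "gene_id": genes[g],
                    "variant_id": genotypes.variants.loc[causal_variant[g], "variant_id"],
                    "decay_effect": decay_eff[g],
                    "baseline_effect": trans_eff[g],
                    "kind": "rdQTL" if decay_eff[g] != 0 else "eQTL",
                }
            )
    qtl_table = pd.DataFrame(
        qtl_rows,
        columns=["gene_id", "variant_id", "decay_effect", "baseline_effect", "kind"],
    )

    truth = TrueParameters(
        k_abs=pd.DataFrame(k_abs, index=genes, columns=individuals),
        lambda_bar=pd.Series(lambda_bar_i, index=individuals, name="lambda_bar"),
        baseline_log2_m0=pd.DataFrame(baseline, index=genes, columns=individuals),
        qtl_table=qtl_table,
    )
    study = SimulatedStudy(
        cube=cube, genotypes=genotypes, annotations=annotations, design=design
    )
    return study, truth
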