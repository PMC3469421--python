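"""Normalization and summarization of raw log2 intensity cubes.

Turns probe- or gene-level intensity cubes into analysis-ready gene x
individual matrices: across-array quantile normalization, detection
filtering at the first and last harvests, probe-to-gene averaging,
SNP-in-probe residual correction, steady-state summarization and the
cell-count standardization used to put profiles back on an absolute scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import ols_slope
from .containers import ExpressionCube

__all__ = [
    "quantile_normalize_arrays",
    "filter_detected_genes",
    "aggregate_probes_to_genes",
    "correct_probe_snp",
    "steady_state_expression",
    "standardize_by_cell_counts",
    "ProbeMap",
]

logger = logging.getLogger(__name__)


@dataclass
class ProbeMap:
    """Probe-to-gene assignment, with optional SNP-in-probe annotations.

    ``mapping`` maps probe_id -> gene_id (many probes to one gene);
    ``probe_snp`` maps probe_id -> variant_id for probes whose 50-mer
    overlaps a known variant (candidates for hybridization artifacts).
    """

    mapping: Dict[str, str]
    probe_snp: Optional[Dict[str, str]] = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        mapping = dict(zip(df["probe_id"], df["gene_id"]))
        probe_snp = None
        if "variant_id" in df.columns:
            sub = df[df["variant_id"].notna() & (df["variant_id"] != ".")]
            probe_snp = dict(zip(sub["probe_id"], sub["variant_id"]))
        return cls(mapping=mapping, probe_snp=probe_snp)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        snp = self.probe_snp or {}
        for probe, gene in self.mapping.items():
            rows.append({"probe_id": probe, "gene_id": gene, "variant_id": snp.get(probe, ".")})
        return pd.DataFrame(rows)


def quantile_normalize_arrays(cube: ExpressionCube) -> ExpressionCube:
    """Force every array (individual x time-point sample) onto the common
    across-array mean distribution.

    Each column keeps its within-array ranks (ties averaged) and takes the
    mean-of-sorted-values reference vector.  Rank-degenerate (all-constant)
    arrays are left unchanged.
    """
    flat = cube.values.reshape(cube.n_features, -1)
    if flat.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    m = flat.shape[0]
    ref = np.sort(flat, axis=0).mean(axis=1)

    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        if col.min() == col.max():
            out[:, j] = col  # rank-degenerate array: leave untouched
            continue
        ranks = stats.rankdata(col, method="average")  # 1..m, ties averaged
        # linear interpolation on the reference at fractional (tied) ranks
        out[:, j] = np.interp(ranks, np.arange(1, m + 1), ref)
    new = cube.copy()
    new.values = out.reshape(cube.values.shape)
    return new


def filter_detected_genes(
    cube: ExpressionCube, min_frac: float = 0.8
) -> Tuple[ExpressionCube, pd.Series]:
    """Keep features detected above background at the untreated time point in
    at least ``min_frac`` of individuals AND at the final time point in at
    least ``min_frac`` of individuals (boundary inclusive).

    Returns the filtered cube and a Series of counts dropped per rule.
    """
    if cube.detection is None:
        raise ValueError(
            "cube has no detection mask; supply one or skip detection filtering"
        )
    det0 = cube.detection[:, :, 0].mean(axis=1)
    detT = cube.detection[:, :, -1].mean(axis=1)
    pass0 = det0 >= min_frac
    passT = detT >= min_frac
    keep = pass0 & passT
    counts = pd.Series(
        {
            "failed_time0": int((~pass0).sum()),
            "failed_final": int((~passT).sum()),
            "dropped": int((~keep).sum()),
            "retained": int(keep.sum()),
        }
    )
    new = ExpressionCube(
        values=cube.values[keep],
        features=cube.features[keep],
        individuals=cube.individuals,
        time_points_h=cube.time_points_h,
        feature_level=cube.feature_level,
        detection=cube.detection[keep],
    )
    return new, counts


def aggregate_probes_to_genes(cube: ExpressionCube, probe_map: ProbeMap) -> ExpressionCube:
    """Average probe intensities into gene intensities.

    The gene value is the unweighted mean of its probes per individual x
    time point.  Probes without a gene assignment are dropped with a warning.
    """
    if cube.feature_level != "probe":
        raise ValueError("cube is not probe-level")
    genes_of = np.array(
        [probe_map.mapping.get(p) for p in cube.features], dtype=object
    )
    unmapped = genes_of == None  # noqa: E711 - element-wise against None
    if unmapped.any():
        logger.warning("dropping %d probes without a gene mapping", int(unmapped.sum()))
    keep = ~unmapped
    genes_of = genes_of[keep]
    values = cube.values[keep]
    detection = None if cube.detection is None else cube.detection[keep]

    gene_ids, inverse = np.unique(genes_of.astype(str), return_inverse=True)
    sums = np.zeros((len(gene_ids),) + values.shape[1:])
    counts = np.zeros(len(gene_ids))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1)
    mean = sums / counts[:, None, None]

    det_out = None
    if detection is not None:
        det_sum = np.zeros_like(sums)
        np.add.at(det_sum, inverse, detection.astype(float))
        # a gene counts as detected where all of its probes are detected
        det_out = det_sum >= counts[:, None, None]
    return ExpressionCube(
        values=mean,
        features=gene_ids.astype(object),
        individuals=cube.individuals,
        time_points_h=cube.time_points_h,
        feature_level="gene",
        detection=det_out,
    )


def correct_probe_snp(
    steady_state: np.ndarray,
    dosages: np.ndarray,
    alpha: float = 0.05,
) -> Tuple[np.ndarray, bool]:
    """Remove the hybridization artifact of a SNP inside the probe sequence.

    Regresses the per-individual steady-state values on the in-probe SNP
    dosage; if the slope is significant at ``alpha`` the (centered) residuals
    replace the measurements, otherwise the input is returned unchanged.
    Returns ``(values, corrected_flag)``.
    """
    y = np.asarray(steady_state, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("steady_state and dosages must be matched 1-D vectors")
    if len(np.unique(g)) < 2:
        return y, False  # monomorphic: regression undefined, leave unchanged
    if len(y) < 3:
        raise ValueError("need at least 3 individuals")
    fit = ols_slope(g, y)
    if fit.p < alpha:
        resid = y - (fit.intercept + fit.slope * g)
        return resid, True
    return y, False


def steady_state_expression(cube: ExpressionCube) -> pd.DataFrame:
    """Steady-state expression: mean log2 intensity across all time points.

    Averaging over the full time course (rather than taking the untreated
    point) makes the summary statistically independent of the fitted decay
    slope under the null, since the OLS slope contrast is orthogonal to the
    mean.
    """
    if cube.feature_level != "gene":
        raise ValueError("steady-state summarization expects a gene-level cube")
    mat = cube.values.mean(axis=2)
    return pd.DataFrame(mat, index=pd.Index(cube.features, name="gene_id"),
                        columns=pd.Index(cube.individuals, name="individual_id"))


def standardize_by_cell_counts(
    cube: ExpressionCube, cells_per_timepoint: np.ndarray
) -> ExpressionCube:
    """Undo the equal-mass artifact for visualization / absolute-scale use.

    Subtracts ``log2(cells_t / cells_0)`` from each time point, so that on a
    noiseless exact-mode study generated with the default design the
    standardized slope equals the absolute decay rate.
    """
    cells = np.asarray(cells_per_timepoint, dtype=float)
    if len(cells) != cube.n_timepoints:
        raise ValueError("cells_per_timepoint length must match the cube")
    if np.any(cells <= 0):
        raise ValueError("cell counts must be positive")
    shift = np.log2(cells / cells[0])
    new = cube.copy()
    new.values = new.values - shift[None, None, :]
    return new
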