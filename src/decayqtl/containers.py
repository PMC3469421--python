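"""In-memory containers shared across the pipeline stages.

The central object is the :class:`ExpressionCube`, a dense log2-intensity
array indexed by feature (probe or gene) x individual x time point, mirroring
the layout of a transcription-arrest time-course experiment in which every
individual is assayed on one array per time point.  Genotypes are carried as
minor-allele dosage matrices with 1-based variant positions (VCF convention);
gene annotations use BED conventions (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCube",
    "GenotypeMatrix",
    "DecayMatrix",
    "MeanCellularRate",
]

#: Required columns of a gene annotation table (BED-like, 0-based half-open).
ANNOTATION_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]

#: Required columns of a study design table.
DESIGN_COLUMNS = ["individual_id", "time_h", "cells", "rna_yield_ng"]


@dataclass
class ExpressionCube:
    """log2 intensities on a feature x individual x time-point grid.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_individuals, n_timepoints)``.
    features, individuals
        String identifiers along the first two axes.
    time_points_h
        Harvest times in hours, strictly increasing, first equal to 0.
    feature_level
        ``"probe"`` or ``"gene"``.
    detection
        Optional boolean mask of the same shape as ``values`` marking
        intensities detected above array background.
    """

    values: np.ndarray
    features: np.ndarray
    individuals: np.ndarray
    time_points_h: np.ndarray
    feature_level: str = "gene"
    detection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.features = np.asarray(self.features, dtype=object)
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.time_points_h = np.asarray(self.time_points_h, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (features x individuals x time)")
        expected = (len(self.features), len(self.individuals), len(self.time_points_h))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )
        if self.feature_level not in ("probe", "gene"):
            raise ValueError("feature_level must be 'probe' or 'gene'")
        if np.any(np.diff(self.time_points_h) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.detection is not None:
            self.detection = np.asarray(self.detection, dtype=bool)
            if self.detection.shape != self.values.shape:
                raise ValueError("detection mask shape must match values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "ExpressionCube":
        return replace(
            self,
            values=self.values.copy(),
            detection=None if self.detection is None else self.detection.copy(),
        )

    # -- long-format interchange ------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long-format table: gene_id/probe_id, individual_id, time_h, log2_intensity."""
        idx = pd.MultiIndex.from_product(
            [self.features, self.individuals, self.time_points_h],
            names=["feature_id", "individual_id", "time_h"],
        )
        df = pd.DataFrame({"log2_intensity": self.values.ravel()}, index=idx)
        if self.detection is not None:
            df["detected"] = self.detection.ravel().astype(int)
        return df.reset_index()

    @classmethod
    def from_long(cls, df: pd.DataFrame, feature_level: str = "gene") -> "ExpressionCube":
        """Build a cube from a long-format table (must be complete on its grid)."""
        features = df["feature_id"].unique()
        individuals = df["individual_id"].unique()
        times = np.sort(df["time_h"].unique())
        pivot = df.set_index(["feature_id", "individual_id", "time_h"])
        full = pd.MultiIndex.from_product(
            [features, individuals, times],
            names=["feature_id", "individual_id", "time_h"],
        )
        pivot = pivot.reindex(full)
        if pivot["log2_intensity"].isna().any():
            raise ValueError("long-format table has missing feature/individual/time cells")
        values = pivot["log2_intensity"].to_numpy().reshape(
            len(features), len(individuals), len(times)
        )
        detection = None
        if "detected" in pivot.columns and not pivot["detected"].isna().any():
            detection = (
                pivot["detected"].to_numpy().reshape(values.shape).astype(bool)
            )
        return cls(
            values=values,
            features=np.asarray(features, dtype=object),
            individuals=np.asarray(individuals, dtype=object),
            time_points_h=times,
            feature_level=feature_level,
            detection=detection,
        )


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages for variants x individuals.

    ``dosages`` holds 0/1/2 counts of the cohort minor allele.  ``variants``
    is a table with columns ``variant_id, chrom, pos, ref, alt`` where ``pos``
    is 1-based (VCF convention).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individuals: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.individuals = np.asarray(self.individuals, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (variants x individuals)")
        if self.dosages.shape[0] != len(self.variants):
            raise ValueError("variant table length must match dosage rows")
        if self.dosages.shape[1] != len(self.individuals):
            raise ValueError("individual list must match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1 or 2 minor-allele copies")
        missing = [c for c in ("variant_id", "chrom", "pos") if c not in self.variants]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per variant: min(f, 1 - f)."""
        f = self.dosages.mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[mask],
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            individuals=self.individuals,
        )


@dataclass
class DecayMatrix:
    """Per gene x individual relative decay-rate estimates.

    ``k`` is positive for transcripts decaying faster than the mean cellular
    rate (the k = 0 reference of the equal-mass design).  ``se`` and ``p``
    come from the per-fit OLS t-test; ``b0`` is the fitted log2 abundance at
    the untreated time point.  ``exact_fit`` marks zero-residual fits.
    """

    k: pd.DataFrame
    se: pd.DataFrame
    p: pd.DataFrame
    b0: pd.DataFrame
    exact_fit: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for name in ("se", "p", "b0"):
            other = getattr(self, name)
            if other.shape != self.k.shape:
                raise ValueError(f"{name} shape must match k")

    @property
    def genes(self) -> pd.Index:
        return self.k.index

    @property
    def individuals(self) -> pd.Index:
        return self.k.columns

    @property
    def median_k(self) -> pd.Series:
        """Per-gene median relative decay rate across individuals."""
        return self.k.median(axis=1, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (gene_id, individual_id, k, se, p, b0)."""
        parts = {
            "k": self.k.stack(),
            "se": self.se.stack(),
            "p": self.p.stack(),
            "b0": self.b0.stack(),
        }
        df = pd.DataFrame(parts)
        df.index.names = ["gene_id", "individual_id"]
        return df.reset_index()


@dataclass
class MeanCellularRate:
    """Mean cellular decay rate lambda-bar (log2-units/h) from the yield design."""

    lambda_bar: float
    se: float
    scope: str = "global"  # "global" or an individual id
    per_individual: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_bar):
            raise ValueError("lambda_bar must be finite")


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check a BED-like gene annotation table and return it with a clean index."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    ann = annotations.reset_index(drop=True)
    if (ann["end"] <= ann["start"]).any():
        raise ValueError("annotation end must exceed start (BED half-open)")
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotations")
    return ann
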