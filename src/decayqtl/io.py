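"""Readers and writers for the pipeline's plain-text formats.

Conventions: expression travels as long-format TSV (gene_id, individual_id,
time_h, log2_intensity); genotypes as either a TSV dosage matrix or a
minimal VCF (GT fields, diploid); gene annotations as BED-like TSV (0-based,
half-open); the harvest design as TSV (individual_id, time_h, cells,
rna_yield_ng).  VCF positions are 1-based; the single BED<->VCF coordinate
conversion lives in :func:`decayqtl.qtl.cis_window`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import pysam

from .containers import (
    ANNOTATION_COLUMNS,
    DESIGN_COLUMNS,
    ExpressionCube,
    GenotypeMatrix,
    validate_annotations,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_annotations",
    "write_annotations",
    "read_design",
    "write_design",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_MISSING_FRAC_MAX = 0.10  # variants missing in more individuals are dropped


def write_expression(cube: ExpressionCube, path: PathLike) -> None:
    df = cube.to_long().rename(columns={"feature_id": f"{cube.feature_level}_id"})
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: PathLike, feature_level: str = "gene") -> ExpressionCube:
    df = pd.read_csv(path, sep="\t")
    id_col = f"{feature_level}_id"
    if id_col not in df.columns:
        raise ValueError(f"expression table must have a {id_col} column")
    df = df.rename(columns={id_col: "feature_id"})
    return ExpressionCube.from_long(df, feature_level=feature_level)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: PathLike) -> None:
    meta = genotypes.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    dos = pd.DataFrame(
        genotypes.dosages, columns=genotypes.individuals
    )
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def _read_dosage_tsv(path: PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("variant_id", "chrom", "pos", "ref", "alt") if c in df.columns]
    if "variant_id" not in meta_cols:
        raise ValueError("dosage TSV must carry a variant_id column")
    individuals = [c for c in df.columns if c not in meta_cols]
    dosages = df[individuals].to_numpy()
    variants = df[meta_cols].copy()
    for c in ("chrom", "pos", "ref", "alt"):
        if c not in variants:
            variants[c] = {"chrom": "chr1", "pos": 0, "ref": "A", "alt": "G"}[c]
    return _recode_to_minor(
        dosages.astype(float), variants, np.asarray(individuals, dtype=object)
    )


def write_vcf(genotypes: GenotypeMatrix, path: PathLike) -> None:
    """Minimal uncompressed VCF v4.2 with GT fields.

    The written ALT allele is the cohort minor allele, so GT allele counts
    equal the stored dosages; re-reading recodes from cohort frequency and
    round-trips exactly.
    """
    path = Path(path)
    chroms = pd.unique(genotypes.variants["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=decayqtl\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(str(i) for i in genotypes.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        order = genotypes.variants.sort_values(["chrom", "pos"]).index
        for i in order:
            row = genotypes.variants.loc[i]
            gts = []
            for d in genotypes.dosages[i]:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}"
                f"\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _recode_to_minor(
    alt_counts: np.ndarray, variants: pd.DataFrame, individuals: np.ndarray
) -> GenotypeMatrix:
    """Alternate-allele counts -> minor-allele dosages, with missing-call
    handling: drop variants missing in more than 10% of individuals, impute
    the rest to the variant's rounded mean dosage."""
    n_ind = alt_counts.shape[1]
    missing = ~np.isfinite(alt_counts)
    frac_missing = missing.mean(axis=1)
    keep = frac_missing <= _MISSING_FRAC_MAX
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d variants with >10%% missing calls", dropped)
    alt_counts = alt_counts[keep]
    missing = missing[keep]
    variants = variants.loc[keep].reset_index(drop=True)

    if missing.any():
        logger.warning(
            "imputed %d missing calls to rounded mean dosage", int(missing.sum())
        )
        means = np.where(
            missing.all(axis=1), 0.0, np.nanmean(np.where(missing, np.nan, alt_counts), axis=1)
        )
        fill = np.round(np.broadcast_to(means[:, None], alt_counts.shape))
        alt_counts = np.where(missing, fill, alt_counts)

    # recode so dosages count the cohort minor allele
    f_alt = alt_counts.mean(axis=1) / 2.0
    flip = f_alt > 0.5
    dosages = np.where(flip[:, None], 2 - alt_counts, alt_counts).astype(np.int8)
    if flip.any():
        variants = variants.copy()
        ref = variants.loc[flip, "ref"].copy()
        variants.loc[flip, "ref"] = variants.loc[flip, "alt"].to_numpy()
        variants.loc[flip, "alt"] = ref.to_numpy()
    return GenotypeMatrix(dosages=dosages, variants=variants, individuals=individuals)


def _read_vcf(path: PathLike) -> GenotypeMatrix:
    vcf = pysam.VariantFile(str(path))
    individuals = np.asarray(list(vcf.header.samples), dtype=object)
    if individuals.size == 0:
        raise ValueError("VCF has no sample columns")
    rows = []
    counts = []
    for n_line, rec in enumerate(vcf.fetch() if vcf.index else vcf):
        try:
            alts = rec.alts or ()
            alt = alts[0] if alts else "."
            line_counts = np.empty(individuals.size)
            for j, sample in enumerate(individuals):
                gt = rec.samples[sample].get("GT")
                if gt is None or all(a is None for a in gt):
                    line_counts[j] = np.nan
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError("non-diploid or half-called GT")
                line_counts[j] = sum(1 for a in gt if a != 0)
            rows.append(
                {
                    "variant_id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                }
            )
            counts.append(line_counts)
        except ValueError as exc:
            raise ValueError(f"malformed VCF record #{n_line + 1} ({rec.chrom}:{rec.pos}): {exc}")
    if not rows:
        raise ValueError("VCF contains no variant records")
    return _recode_to_minor(np.vstack(counts), pd.DataFrame(rows), individuals)


def read_genotypes(path: PathLike) -> GenotypeMatrix:
    """Load genotypes from VCF (``.vcf``/``.vcf.gz``) or TSV dosage matrix.

    Dosages are returned as 0/1/2 minor-allele counts, recoded from
    alternate-allele counts using the cohort allele frequency.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def read_annotations(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_annotations(df[ANNOTATION_COLUMNS])


def write_annotations(annotations: pd.DataFrame, path: PathLike) -> None:
    validate_annotations(annotations)[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    return df[DESIGN_COLUMNS]


def write_design(design: pd.DataFrame, path: PathLike) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)
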