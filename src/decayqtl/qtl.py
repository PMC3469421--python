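"""cis-QTL mapping for decay rates (rdQTLs) and steady-state expression
(eQTLs) with hidden-confounder PC correction and permutation min-p FDR.

Per gene, the (already PC-corrected) phenotype is regressed on minor-allele
dosage for every variant in the cis-candidate window — 25 kb upstream of the
transcription start to 25 kb downstream of the transcription end, MAF
strictly above 10% — under an additive model:

    r_i = mu + gamma * g_ij + eps_i

The per-gene minimum p over cis variants is calibrated against permutations
that reshuffle individual labels of the phenotype (the same shuffle for all
genes within a permutation), whose per-gene minimum p-values are pooled into
the empirical null fed to :func:`decayqtl.assoc.permutation_fdr`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import ols_slope
from .assoc import FdrTable, permutation_fdr
from .containers import GenotypeMatrix, validate_annotations

__all__ = [
    "regress_out_pcs",
    "cis_window",
    "cis_variants",
    "map_cis_qtl",
    "QtlScan",
    "effects_at_variants",
    "eqtl_rdqtl_concordance",
    "enrichment_resample",
    "annotation_qq",
    "normal_scores",
]

logger = logging.getLogger(__name__)

WINDOW_BP = 25_000


def normal_scores(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rank-based inverse-normal transform across individuals.

    Standard practice for eQTL phenotypes: each gene's values are replaced by
    quantiles of the standard normal at (rank - 0.5) / n, making every gene
    marginally Gaussian while preserving ranks.
    """
    vals = phenotype.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    n = vals.shape[1]
    ranks = stats.rankdata(vals, axis=1, method="average")
    out = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=phenotype.index, columns=phenotype.columns)


def regress_out_pcs(phenotype: pd.DataFrame, n_pcs: int = 13) -> pd.DataFrame:
    """Remove hidden confounders via PCA on the individual x individual
    correlation matrix of the phenotype.

    The top ``n_pcs`` eigenvectors (individual loadings) plus an intercept
    are regressed out of every gene's vector; residuals are returned.  With
    ``n_pcs = 0`` only the intercept is removed (row centering).
    """
    n_ind = phenotype.shape[1]
    if n_pcs >= n_ind:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    if n_pcs < 0:
        raise ValueError("n_pcs must be non-negative")
    Y = phenotype.to_numpy(dtype=float)
    X = np.ones((n_ind, 1))
    if n_pcs > 0:
        corr = np.corrcoef(Y, rowvar=False)  # individuals x individuals
        eigval, eigvec = np.linalg.eigh(corr)
        top = eigvec[:, np.argsort(eigval)[::-1][:n_pcs]]
        X = np.hstack([X, top])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return pd.DataFrame(resid.T, index=phenotype.index, columns=phenotype.columns)


def cis_window(annotation_row: Mapping, window_bp: int = WINDOW_BP) -> Tuple[int, int]:
    """1-based inclusive cis-candidate bounds for a BED-convention gene record.

    The BED half-open span [start, end) covers 1-based positions start+1..end;
    the window extends ``window_bp`` beyond both transcript ends, clamped at 1.
    """
    lo = max(1, int(annotation_row["start"]) + 1 - window_bp)
    hi = int(annotation_row["end"]) + window_bp
    return lo, hi


def cis_variants(
    annotation_row: Mapping,
    genotypes: GenotypeMatrix,
    window_kb: float = 25.0,
    maf_min: float = 0.10,
) -> np.ndarray:
    """Indices of variants inside a gene's cis window with MAF strictly above
    ``maf_min`` (boundary positions included, boundary MAF excluded)."""
    lo, hi = cis_window(annotation_row, window_bp=int(window_kb * 1000))
    v = genotypes.variants
    in_window = (
        (v["chrom"].to_numpy() == annotation_row["chrom"])
        & (v["pos"].to_numpy() >= lo)
        & (v["pos"].to_numpy() <= hi)
    )
    return np.flatnonzero(in_window & (genotypes.maf > maf_min))


@dataclass
class QtlScan:
    """Result of one cis scan: per-gene best variant and permutation FDR."""

    results: pd.DataFrame  # gene_id index; best_variant_id, gamma, p_best, q, n_variants_tested
    perm_min_p: pd.DataFrame  # genes x permutations
    fdr: FdrTable
    per_variant: pd.DataFrame  # gene_id, variant_id, gamma, t, p (observed scan)

    def significant(self, target_fdr: Optional[float] = None) -> pd.Index:
        thr = self.fdr.target_fdr if target_fdr is None else target_fdr
        return self.results.index[self.results["q"] <= thr]


def _scan_gene(y: np.ndarray, G: np.ndarray):
    """Vectorized simple regressions of one phenotype vector on each dosage row."""
    fit = ols_slope(G, np.broadcast_to(y, G.shape))
    return fit.slope, fit.t, fit.p


def map_cis_qtl(
    phenotype: pd.DataFrame,
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    n_perms: int = 3,
    seed=0,
    window_kb: float = 25.0,
    maf_min: float = 0.10,
    target_fdr: float = 0.15,
) -> QtlScan:
    """Additive cis scan with permutation min-p FDR.

    ``phenotype`` (gene x individual) is assumed already PC-corrected.  Genes
    without qualifying cis variants are omitted (counted in the log).
    """
    ann = validate_annotations(annotations)
    ann = ann.set_index("gene_id", drop=False)
    common = phenotype.index.intersection(ann.index)
    if len(common) == 0:
        raise ValueError("no genes shared between phenotype and annotations")
    if not np.array_equal(np.asarray(genotypes.individuals, dtype=object),
                          np.asarray(phenotype.columns, dtype=object)):
        raise ValueError("genotype and phenotype individuals must match in order")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ind = phenotype.shape[1]
    perms = [rng.permutation(n_ind) for _ in range(n_perms)]

    rows = []
    per_variant_rows = []
    perm_min = {}
    skipped = 0
    for gene in common:
        vidx = cis_variants(ann.loc[gene], genotypes, window_kb=window_kb, maf_min=maf_min)
        y = phenotype.loc[gene].to_numpy(dtype=float)
        if len(vidx) == 0 or not np.all(np.isfinite(y)):
            skipped += 1
            continue
        G = genotypes.dosages[vidx].astype(float)
        gamma, tval, pval = _scan_gene(y, G)
        best = int(np.argmin(pval))
        var_ids = genotypes.variants.loc[vidx, "variant_id"].to_numpy()
        per_variant_rows.append(
            pd.DataFrame(
                {"gene_id": gene, "variant_id": var_ids, "gamma": gamma, "t": tval, "p": pval}
            )
        )
        mins = np.empty(n_perms)
        for j, idx in enumerate(perms):
            _, _, p_perm = _scan_gene(y[idx], G)
            mins[j] = p_perm.min()
        perm_min[gene] = mins
        rows.append(
            {
                "gene_id": gene,
                "best_variant_id": var_ids[best],
                "gamma": float(gamma[best]),
                "p_best": float(pval[best]),
                "n_variants_tested": len(vidx),
            }
        )
    if skipped:
        logger.info("skipped %d genes with no qualifying cis variants", skipped)
    if not rows:
        raise ValueError("no genes could be tested")
    results = pd.DataFrame(rows).set_index("gene_id")
    perm_min_p = pd.DataFrame(perm_min).T
    perm_min_p.index.name = "gene_id"
    fdr = permutation_fdr(
        results["p_best"], perm_min_p.to_numpy().ravel(), n_perms, target_fdr=target_fdr
    )
    results["q"] = fdr.q
    per_variant = pd.concat(per_variant_rows, ignore_index=True)
    return QtlScan(results=results, perm_min_p=perm_min_p, fdr=fdr, per_variant=per_variant)


def effects_at_variants(
    phenotype: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Effect of a named variant on a named gene's phenotype, per row of
    ``pairs`` (columns gene_id, variant_id).  Used to evaluate decay effects
    at each gene's best eQTL SNP."""
    vindex = pd.Index(genotypes.variants["variant_id"])
    rows = []
    for gene, variant in pairs[["gene_id", "variant_id"]].itertuples(index=False):
        if gene not in phenotype.index or variant not in vindex:
            raise KeyError(f"unknown gene/variant pair ({gene}, {variant})")
        y = phenotype.loc[gene].to_numpy(dtype=float)
        g = genotypes.dosages[vindex.get_loc(variant)].astype(float)
        fit = ols_slope(g, y)
        rows.append(
            {"gene_id": gene, "variant_id": variant, "gamma": float(fit.slope),
             "t": float(fit.t), "p": float(fit.p)}
        )
    return pd.DataFrame(rows)


def eqtl_rdqtl_concordance(
    eqtl_effects: pd.DataFrame, decay_effects: pd.DataFrame
) -> pd.DataFrame:
    """Allelic sign rule at joint QTLs.

    Both tables carry (gene_id, variant_id, gamma) estimated at the SAME
    variant with the SAME minor-allele coding.  "concordant" means the minor
    allele that lowers expression speeds decay — opposite gamma signs;
    matching signs are "discordant"; a zero effect is "undefined".
    """
    merged = eqtl_effects.merge(
        decay_effects, on="gene_id", suffixes=("_expr", "_decay"), how="inner"
    )
    if (merged["variant_id_expr"] != merged["variant_id_decay"]).any():
        raise ValueError("effects must be evaluated at the same variant per gene")
    prod = np.sign(merged["gamma_expr"]) * np.sign(merged["gamma_decay"])
    label = np.where(prod < 0, "concordant", np.where(prod > 0, "discordant", "undefined"))
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "variant_id": merged["variant_id_expr"],
            "eqtl_sign": np.sign(merged["gamma_expr"]).astype(int),
            "rdqtl_sign": np.sign(merged["gamma_decay"]).astype(int),
            "label": label,
        }
    )


def enrichment_resample(
    best_snp_decay_p: pd.Series,
    significant_eqtl_genes: Iterable,
    expression_levels: pd.Series,
    n_draws: int = 1000,
    seed=0,
    decay_p_threshold: float = 0.05,
) -> Tuple[int, np.ndarray, float]:
    """Expression-matched resampling test for decay effects at eQTL SNPs.

    ``best_snp_decay_p`` holds, for every gene, the decay-association p-value
    at that gene's best eQTL SNP.  The observed statistic is the number of
    significant-eQTL genes whose value falls below ``decay_p_threshold``; the
    null re-draws gene sets of the same size whose per-decile expression
    histogram exactly matches the significant set's, ``n_draws`` times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = pd.Index(significant_eqtl_genes)
    pool = best_snp_decay_p.dropna()
    expr = expression_levels.reindex(pool.index)
    if expr.isna().any():
        raise ValueError("expression levels missing for some genes in the pool")
    if not sig.isin(pool.index).all():
        raise ValueError("significant genes must be a subset of the scored pool")

    deciles = pd.qcut(expr.rank(method="first"), 10, labels=False)
    sig_dec = deciles.reindex(sig)
    need = sig_dec.value_counts().sort_index()
    groups = {d: deciles.index[deciles == d].to_numpy() for d in range(10)}
    for d, n_need in need.items():
        if n_need > len(groups[d]):
            raise ValueError(f"expression decile {d} has too few genes to match")

    hits = pool < decay_p_threshold
    observed = int(hits.reindex(sig).sum())
    null_counts = np.empty(n_draws, dtype=int)
    for b in range(n_draws):
        drawn = np.concatenate(
            [rng.choice(groups[d], size=int(n_need), replace=False)
             for d, n_need in need.items()]
        )
        null_counts[b] = int(hits.reindex(drawn).sum())
    p = (1 + int((null_counts >= observed).sum())) / (n_draws + 1)
    return observed, null_counts, p


def annotation_qq(
    assoc_p: pd.Series, annotation_sets: Mapping[str, Iterable]
) -> Tuple[pd.DataFrame, pd.Series]:
    """Observed vs expected -log10(p) quantiles per variant annotation set.

    Returns a long table (set, expected, observed) suitable for QQ plotting
    and a per-set inflation summary, the ratio of median observed to median
    expected -log10(p).  Empty sets are skipped with a warning.
    """
    tables = []
    inflation = {}
    for name, variants in annotation_sets.items():
        p = assoc_p.reindex(pd.Index(variants)).dropna().to_numpy()
        if p.size == 0:
            logger.warning("annotation set %s is empty; skipped", name)
            continue
        obs = -np.log10(np.sort(p))  # most significant first
        exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
        tables.append(pd.DataFrame({"set": name, "expected": exp, "observed": obs}))
        inflation[name] = float(np.median(obs) / np.median(exp))
    if not tables:
        raise ValueError("all annotation sets were empty")
    return pd.concat(tables, ignore_index=True), pd.Series(inflation, name="inflation")
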