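"""End-to-end pipeline driver.

Runs the stages in their fixed order — preprocess -> decay fit ->
fast/slow classification -> decay-vs-expression association -> PC
correction -> cis-QTL mapping (decay and expression) -> eQTL/rdQTL
concordance -> overlap summary — writes every stage output as TSV, and
records a manifest (input hashes, seed, parameters, filter counts) so a
re-run with the same configuration reproduces outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import decay as decay_mod
from . import io as io_mod
from . import overlap as overlap_mod
from . import preprocess as pre_mod
from . import qtl as qtl_mod

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    expression: str
    genotypes: str
    annotations: str
    design: Optional[str] = None
    probe_map: Optional[str] = None
    out_dir: str = "decayqtl_out"
    # stage parameters
    quantile_normalize: bool = True
    detection_min_frac: float = 0.8
    class_alpha: float = 0.1
    class_min_frac: float = 0.8
    window_kb: float = 25.0
    maf_min: float = 0.10
    n_pcs: int = 13
    n_perms: int = 3
    fdr_assoc: float = 0.10
    fdr_qtl: float = 0.15
    tail_q: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression", "genotypes", "annotations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name, lo, hi in (
            ("detection_min_frac", 0, 1), ("class_alpha", 0, 1),
            ("class_min_frac", 0, 1), ("maf_min", 0, 0.5),
            ("fdr_assoc", 0, 1), ("fdr_qtl", 0, 1), ("tail_q", 0, 0.5),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "counts": {},
    }
    for name in ("expression", "genotypes", "annotations", "design", "probe_map"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stage = "load"
    try:
        feature_level = "probe" if config.probe_map else "gene"
        cube = io_mod.read_expression(config.expression, feature_level=feature_level)
        genotypes = io_mod.read_genotypes(config.genotypes)
        annotations = io_mod.read_annotations(config.annotations)
        design = io_mod.read_design(config.design) if config.design else None

        stage = "preprocess"
        if config.quantile_normalize:
            cube = pre_mod.quantile_normalize_arrays(cube)
        if cube.detection is not None:
            cube, drop_counts = pre_mod.filter_detected_genes(
                cube, min_frac=config.detection_min_frac
            )
            manifest["counts"]["detection_filter"] = drop_counts.to_dict()
        if config.probe_map:
            pmap = pre_mod.ProbeMap.from_frame(pd.read_csv(config.probe_map, sep="\t"))
            cube = pre_mod.aggregate_probes_to_genes(cube, pmap)
        manifest["counts"]["genes_analyzed"] = int(cube.n_features)

        stage = "fit-decay"
        decay = decay_mod.fit_decay_matrix(cube)
        decay.to_frame().to_csv(out / "decay_matrix.tsv", sep="\t", index=False)
        steady = pre_mod.steady_state_expression(cube)
        steady.to_csv(out / "steady_state.tsv", sep="\t")

        if config.probe_map:
            # SNP-in-probe correction applies to the steady-state vector only
            pmap_df = pd.read_csv(config.probe_map, sep="\t")
            pm = pre_mod.ProbeMap.from_frame(pmap_df)
            if pm.probe_snp:
                vindex = pd.Index(genotypes.variants["variant_id"])
                n_corrected = 0
                for probe, variant in pm.probe_snp.items():
                    gene = pm.mapping.get(probe)
                    if gene not in steady.index or variant not in vindex:
                        continue
                    dos = genotypes.dosages[vindex.get_loc(variant)]
                    new_vals, corrected = pre_mod.correct_probe_snp(
                        steady.loc[gene].to_numpy(), dos
                    )
                    if corrected:
                        steady.loc[gene] = new_vals
                        n_corrected += 1
                manifest["counts"]["snp_in_probe_corrected"] = n_corrected

        if design is not None:
            first = design[design["individual_id"] == design["individual_id"].iloc[0]]
            rate = decay_mod.estimate_mean_cellular_rate(
                first["cells"], first["rna_yield_ng"], first["time_h"]
            )
            manifest["mean_cellular_rate"] = {
                "lambda_bar": rate.lambda_bar, "se": rate.se,
            }

        stage = "classify"
        classes = decay_mod.classify_decay_genes(
            decay, alpha=config.class_alpha, min_frac=config.class_min_frac
        )
        cls_out = pd.concat([classes.labels, classes.counts], axis=1)
        cls_out.to_csv(out / "decay_classes.tsv", sep="\t")
        manifest["counts"]["fast_genes"] = int((classes.labels == "fast").sum())
        manifest["counts"]["slow_genes"] = int((classes.labels == "slow").sum())

        stage = "assoc"
        rng = np.random.default_rng(config.seed)
        gene_assoc = assoc_mod.decay_expression_association(steady, decay.k)
        null_p = []
        for perm in assoc_mod.permute_decay_matrix(decay.k, config.n_perms, rng):
            null_p.append(
                assoc_mod.decay_expression_association(steady, perm).p.dropna().to_numpy()
            )
        fdr = assoc_mod.permutation_fdr(
            gene_assoc.p, np.concatenate(null_p), config.n_perms,
            target_fdr=config.fdr_assoc,
        )
        assoc_out = gene_assoc.table.assign(q=fdr.q)
        assoc_out.to_csv(out / "decay_expression_assoc.tsv", sep="\t")
        sig = assoc_out[assoc_out["q"] <= config.fdr_assoc]
        manifest["counts"]["assoc_concordant"] = int((sig["direction"] == "concordant").sum())
        manifest["counts"]["assoc_discordant"] = int((sig["direction"] == "discordant").sum())
        tail = assoc_mod.tail_overlap(decay.median_k, steady.mean(axis=1), config.tail_q)
        manifest["counts"]["tail_overlap_genes"] = int(len(tail))

        stage = "map-qtl"
        n_pcs = min(config.n_pcs, decay.k.shape[1] - 2)
        decay_corr = qtl_mod.regress_out_pcs(decay.k, n_pcs=n_pcs)
        expr_corr = qtl_mod.regress_out_pcs(qtl_mod.normal_scores(steady), n_pcs=n_pcs)
        rd_scan = qtl_mod.map_cis_qtl(
            decay_corr, genotypes, annotations, n_perms=config.n_perms,
            seed=rng, window_kb=config.window_kb, maf_min=config.maf_min,
            target_fdr=config.fdr_qtl,
        )
        e_scan = qtl_mod.map_cis_qtl(
            expr_corr, genotypes, annotations, n_perms=config.n_perms,
            seed=rng, window_kb=config.window_kb, maf_min=config.maf_min,
            target_fdr=config.fdr_qtl,
        )
        rd_scan.results.to_csv(out / "rdqtl.tsv", sep="\t")
        e_scan.results.to_csv(out / "eqtl.tsv", sep="\t")
        manifest["counts"]["rdqtl_genes"] = int(len(rd_scan.significant()))
        manifest["counts"]["eqtl_genes"] = int(len(e_scan.significant()))

        stage = "concordance"
        sig_e = e_scan.significant()
        concordance = pd.DataFrame(
            columns=["gene_id", "variant_id", "eqtl_sign", "rdqtl_sign", "label"]
        )
        if len(sig_e) > 0:
            pairs = e_scan.results.loc[sig_e, ["best_variant_id"]].rename(
                columns={"best_variant_id": "variant_id"}
            ).reset_index()
            pairs = pairs[pairs["gene_id"].isin(decay_corr.index)]
            if len(pairs):
                e_eff = qtl_mod.effects_at_variants(expr_corr, genotypes, pairs)
                d_eff = qtl_mod.effects_at_variants(decay_corr, genotypes, pairs)
                concordance = qtl_mod.eqtl_rdqtl_concordance(e_eff, d_eff)
        concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
        manifest["counts"]["joint_concordant"] = int((concordance["label"] == "concordant").sum())
        manifest["counts"]["joint_discordant"] = int((concordance["label"] == "discordant").sum())

        stage = "overlap"
        sig_rd = set(rd_scan.significant())
        both = sig_rd & set(sig_e)
        n_total = int(len(e_scan.results))
        if n_total > 0 and len(sig_e) > 0:
            exp, exp_round = overlap_mod.expected_overlap(
                len(sig_e), len(sig_rd), n_total
            )
            manifest["overlap"] = {
                "n_eqtl": int(len(sig_e)),
                "n_rdqtl": int(len(sig_rd)),
                "n_joint": int(len(both)),
                "expected_by_chance": exp,
                "p_hypergeom": overlap_mod.overlap_significance(
                    len(sig_e), len(sig_rd), len(both), n_total
                ),
            }
        pi0 = overlap_mod.pi0_storey_bootstrap(
            rd_scan.results["p_best"].to_numpy(), seed=config.seed
        ) if len(rd_scan.results) >= 50 else None
        if pi0 is not None:
            manifest["pi0_rdqtl_minp"] = {
                "pi0_hat": pi0.pi0_hat, "lambda": pi0.selected_lambda,
                "ci": list(pi0.bootstrap_ci),
            }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
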