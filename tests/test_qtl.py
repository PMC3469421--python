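"""cis-QTL mapping: PC correction, window logic, scans, concordance,
expression-matched enrichment resampling and QQ summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import ols_oracle
from decayqtl import (
    SimConfig,
    annotation_qq,
    cis_variants,
    effects_at_variants,
    enrichment_resample,
    eqtl_rdqtl_concordance,
    fit_decay_matrix,
    map_cis_qtl,
    normal_scores,
    regress_out_pcs,
    simulate_study,
)
from decayqtl.containers import GenotypeMatrix


def small_genotypes(dosages, positions, chrom="chr1"):
    dosages = np.asarray(dosages)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(dosages))],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    inds = np.array([f"i{j}" for j in range(dosages.shape[1])], dtype=object)
    return GenotypeMatrix(dosages=dosages, variants=variants, individuals=inds)


class TestRegressOutPcs:
    def test_zero_pcs_row_centers(self, rng):
        pheno = pd.DataFrame(rng.normal(size=(10, 8)))
        out = regress_out_pcs(pheno, n_pcs=0)
        expected = pheno.sub(pheno.mean(axis=1), axis=0)
        assert np.allclose(out.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_residuals_orthogonal_to_eigenvectors(self, rng):
        pheno = pd.DataFrame(rng.normal(size=(60, 20)))
        n_pcs = 4
        out = regress_out_pcs(pheno, n_pcs=n_pcs)
        corr = np.corrcoef(pheno.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        top = eigvec[:, np.argsort(eigval)[::-1][:n_pcs]]
        proj = out.to_numpy() @ top
        assert np.abs(proj).max() < 1e-8

    def test_rank_one_phenotype_fully_removed(self, rng):
        """A single individual-direction times gene loadings vanishes after
        removing one PC.  The correlation-matrix eigenvector recovers the
        direction up to per-individual signs, so the direction is taken with
        equal magnitudes (the identifiable case under correlation PCA)."""
        load = rng.normal(size=30)
        direction = rng.choice([-1.5, 1.5], size=12)
        pheno = pd.DataFrame(np.outer(load, direction) + 5.0)
        out = regress_out_pcs(pheno, n_pcs=1)
        assert np.abs(out.to_numpy()).max() < 1e-8

    def test_too_many_pcs_error(self, rng):
        pheno = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            regress_out_pcs(pheno, n_pcs=4)


class TestCisVariants:
    ann = {"chrom": "chr1", "start": 100_000, "end": 120_000, "strand": "+",
           "gene_id": "g"}

    def _geno(self, positions, dosage_row=None):
        n = len(positions)
        rng = np.random.default_rng(0)
        d = rng.integers(0, 2, size=(n, 20)) if dosage_row is None else dosage_row
        return small_genotypes(d, positions)

    def test_boundary_positions_inclusive(self):
        # transcript spans 1-based 100001..120000; window 75001..145000
        geno = self._geno([75_001, 75_000, 145_000, 145_001])
        idx = cis_variants(self.ann, geno, maf_min=0.0)
        assert list(idx) == [0, 2]

    def test_maf_strictly_greater(self):
        n_ind = 20
        d_low = np.r_[np.ones(4, dtype=int), np.zeros(n_ind - 4)]  # MAF 0.10
        d_ok = np.r_[np.ones(5, dtype=int), np.zeros(n_ind - 5)]   # MAF 0.125
        geno = small_genotypes(np.vstack([d_low, d_ok]), [110_000, 110_001])
        idx = cis_variants(self.ann, geno, maf_min=0.10)
        assert list(idx) == [1]

    def test_planted_variants_always_in_window(self, default_study):
        study, truth = default_study
        ann = study.annotations.set_index("gene_id", drop=False)
        vindex = pd.Index(study.genotypes.variants["variant_id"])
        for row in truth.qtl_table.itertuples():
            idx = cis_variants(ann.loc[row.gene_id], study.genotypes, maf_min=0.0)
            assert vindex.get_loc(row.variant_id) in idx


class TestMapCisQtl:
    def test_per_variant_stats_match_oracle(self, rng):
        cfg = SimConfig(seed=21, n_genes=12, n_individuals=25, frac_rdqtl=0.25,
                        decay_effect_a=0.3)
        study, _ = simulate_study(cfg)
        dm = fit_decay_matrix(study.cube)
        pheno = dm.k
        scan = map_cis_qtl(pheno, study.genotypes, study.annotations,
                           n_perms=2, seed=0)
        vindex = pd.Index(study.genotypes.variants["variant_id"])
        sample = scan.per_variant.sample(15, random_state=1)
        for row in sample.itertuples():
            y = pheno.loc[row.gene_id].to_numpy()
            g = study.genotypes.dosages[vindex.get_loc(row.variant_id)].astype(float)
            oracle = ols_oracle(g, y)
            assert row.gamma == pytest.approx(oracle["slope"], abs=1e-10)
            assert row.p == pytest.approx(oracle["p"], abs=1e-10)

    def test_strong_planted_effect_is_found(self):
        cfg = SimConfig(seed=22, n_genes=40, n_individuals=50, frac_rdqtl=0.2,
                        decay_effect_a=0.5, noise_sd_log2=0.1,
                        maf_range=(0.3, 0.5))
        study, truth = simulate_study(cfg)
        dm = fit_decay_matrix(study.cube)
        scan = map_cis_qtl(dm.k, study.genotypes, study.annotations,
                           n_perms=3, seed=1)
        planted = truth.qtl_table.query("kind == 'rdQTL'").set_index("gene_id")
        hits = 0
        for gene, row in planted.iterrows():
            res = scan.results.loc[gene]
            if res["best_variant_id"] == row["variant_id"]:
                hits += 1
                assert np.sign(res["gamma"]) == np.sign(row["decay_effect"])
        assert hits >= 0.8 * len(planted)

    def test_gamma_invariances(self, rng):
        cfg = SimConfig(seed=23, n_genes=8, n_individuals=20)
        study, _ = simulate_study(cfg)
        dm = fit_decay_matrix(study.cube)
        scan = map_cis_qtl(dm.k, study.genotypes, study.annotations, n_perms=1, seed=5)
        shifted = map_cis_qtl(dm.k + 7.0, study.genotypes, study.annotations,
                              n_perms=1, seed=5)
        assert np.allclose(scan.results["gamma"], shifted.results["gamma"], atol=1e-10)
        flipped_geno = GenotypeMatrix(
            dosages=2 - study.genotypes.dosages,
            variants=study.genotypes.variants.copy(),
            individuals=study.genotypes.individuals,
        )
        flipped = map_cis_qtl(dm.k, flipped_geno, study.annotations, n_perms=1, seed=5)
        assert np.allclose(scan.results["gamma"], -flipped.results["gamma"], atol=1e-10)
        assert np.allclose(scan.results["p_best"], flipped.results["p_best"], atol=1e-10)

    def test_perm_min_p_below_observed_with_signal(self):
        """Observed min-p stochastically dominates the permutation null
        (one-sided) when effects are planted."""
        from scipy import stats

        cfg = SimConfig(seed=24, n_genes=100, n_individuals=40, frac_rdqtl=0.5,
                        decay_effect_a=0.4, maf_range=(0.3, 0.5))
        study, _ = simulate_study(cfg)
        dm = fit_decay_matrix(study.cube)
        scan = map_cis_qtl(dm.k, study.genotypes, study.annotations, n_perms=5, seed=2)
        res = stats.ks_2samp(
            scan.results["p_best"], scan.perm_min_p.to_numpy().ravel(),
            alternative="greater",
        )
        assert res.pvalue < 1e-6


class TestConcordance:
    def _effects(self, gammas):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(gammas))],
             "variant_id": [f"v{i}" for i in range(len(gammas))],
             "gamma": gammas}
        )

    def test_sign_rule(self):
        e = self._effects([-0.4, -0.4, 0.3])
        d = self._effects([+0.2, -0.2, 0.0])
        out = eqtl_rdqtl_concordance(e, d)
        assert list(out["label"]) == ["concordant", "discordant", "undefined"]

    def test_variant_mismatch_errors(self):
        e = self._effects([-0.4])
        d = self._effects([0.2])
        d.loc[0, "variant_id"] = "other"
        with pytest.raises(ValueError):
            eqtl_rdqtl_concordance(e, d)


class TestEnrichmentResample:
    def _inputs(self, rng, n=200):
        genes = pd.Index([f"g{i}" for i in range(n)])
        p = pd.Series(rng.uniform(size=n), index=genes)
        expr = pd.Series(rng.normal(size=n), index=genes)
        return genes, p, expr

    def test_null_sets_give_central_p(self, rng):
        ps = []
        genes, p, expr = self._inputs(rng)
        for _ in range(20):
            sig = rng.choice(genes, size=40, replace=False)
            _, _, pv = enrichment_resample(p, sig, expr, n_draws=100, seed=rng)
            ps.append(pv)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.15)

    def test_extreme_enrichment_minimal_p(self, rng):
        genes, p, expr = self._inputs(rng)
        p.iloc[:40] = 1e-9          # only the significant set has decay hits
        p.iloc[40:] = 0.9
        sig = genes[:40]
        obs, null, pv = enrichment_resample(p, sig, expr, n_draws=200, seed=1)
        assert obs == 40
        assert pv == pytest.approx(1 / 201, abs=1e-12)

    def test_decile_matching_exact(self, rng):
        genes, p, expr = self._inputs(rng)
        sig = expr.nlargest(30).index  # deliberately skewed expression
        deciles = pd.qcut(expr.rank(method="first"), 10, labels=False)
        need = deciles.reindex(sig).value_counts().sort_index()
        # run once with a single draw and check the matched histogram
        rng2 = np.random.default_rng(0)
        obs, null, _ = enrichment_resample(p, sig, expr, n_draws=5, seed=rng2)
        assert len(null) == 5  # constraint satisfiable despite skew


class TestAnnotationQq:
    def test_uniform_set_has_unit_inflation(self, rng):
        p = pd.Series(rng.uniform(size=2000),
                      index=[f"v{i}" for i in range(2000)])
        table, inflation = annotation_qq(p, {"all": p.index})
        assert inflation["all"] == pytest.approx(1.0, abs=0.1)

    def test_constant_extreme_set(self):
        p = pd.Series(1e-6, index=[f"v{i}" for i in range(100)])
        table, _ = annotation_qq(p, {"hits": p.index})
        assert np.allclose(table["observed"], 6.0)

    def test_planted_set_more_inflated_than_background(self):
        cfg = SimConfig(seed=25, n_genes=80, n_individuals=40, frac_rdqtl=0.4,
                        decay_effect_a=0.4, maf_range=(0.3, 0.5))
        study, truth = simulate_study(cfg)
        dm = fit_decay_matrix(study.cube)
        scan = map_cis_qtl(dm.k, study.genotypes, study.annotations, n_perms=1, seed=3)
        per_var = scan.per_variant.groupby("variant_id")["p"].min()
        planted = pd.Index(truth.qtl_table["variant_id"])
        background = per_var.index.difference(planted)
        _, inflation = annotation_qq(
            per_var, {"planted": planted, "background": background}
        )
        assert inflation["planted"] > inflation["background"]
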