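"""Decay-rate estimation, classification and feature correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import TIME_POINTS, ols_oracle
from decayqtl import (
    classify_decay_genes,
    estimate_mean_cellular_rate,
    feature_rank_correlation,
    fit_decay_matrix,
    fit_decay_rate,
    to_absolute_rates,
)
from decayqtl.containers import DecayMatrix, MeanCellularRate


class TestFitDecayRate:
    def test_flat_series_has_zero_rate_and_no_evidence(self):
        est = fit_decay_rate([8, 8, 8, 8, 8], TIME_POINTS)
        assert est.k == 0.0 and est.p == 1.0 and est.exact_fit

    def test_exact_linear_series(self):
        y = 10.0 - 0.5 * TIME_POINTS
        est = fit_decay_rate(y, TIME_POINTS)
        assert est.k == pytest.approx(0.5, abs=1e-12)
        assert est.b0 == pytest.approx(10.0, abs=1e-12)
        assert est.exact_fit and est.p == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        y = 9.0 - 0.3 * TIME_POINTS + rng.normal(0, 0.2, size=5)
        est = fit_decay_rate(y, TIME_POINTS)
        oracle = ols_oracle(TIME_POINTS, y)
        assert est.k == pytest.approx(-oracle["slope"], abs=1e-10)
        assert est.se == pytest.approx(oracle["se"], abs=1e-10)
        assert est.p == pytest.approx(oracle["p"], abs=1e-10)
        assert est.b0 == pytest.approx(oracle["intercept"], abs=1e-10)

    def test_too_few_timepoints_error(self):
        with pytest.raises(ValueError):
            fit_decay_rate([1.0, 2.0], [0.0, 1.0])

    def test_nonfinite_error(self):
        with pytest.raises(ValueError):
            fit_decay_rate([1.0, np.nan, 2.0], [0.0, 1.0, 2.0])


class TestFitDecayMatrix:
    def test_noiseless_identity(self, noiseless_study):
        study, truth = noiseless_study
        dm = fit_decay_matrix(study.cube)
        assert np.allclose(dm.k.to_numpy(), truth.k_relative.to_numpy(), atol=1e-10)

    def test_matrix_agrees_with_per_series_fits(self, default_study, rng):
        study, _ = default_study
        dm = fit_decay_matrix(study.cube)
        for _ in range(10):
            g = rng.integers(study.cube.n_features)
            i = rng.integers(study.cube.n_individuals)
            single = fit_decay_rate(study.cube.values[g, i], TIME_POINTS)
            assert dm.k.iloc[g, i] == pytest.approx(single.k, abs=1e-12)
            assert dm.p.iloc[g, i] == pytest.approx(single.p, abs=1e-12)

    def test_single_individual_median_is_that_individual(self, noiseless_study):
        study, _ = noiseless_study
        from decayqtl.containers import ExpressionCube

        one = ExpressionCube(
            values=study.cube.values[:, :1, :],
            features=study.cube.features,
            individuals=study.cube.individuals[:1],
            time_points_h=study.cube.time_points_h,
        )
        dm = fit_decay_matrix(one)
        assert dm.median_k.equals(dm.k.iloc[:, 0])

    def test_median_invariant_to_individual_order(self, default_study, rng):
        study, _ = default_study
        dm = fit_decay_matrix(study.cube)
        perm = rng.permutation(study.cube.n_individuals)
        from decayqtl.containers import ExpressionCube

        shuffled = ExpressionCube(
            values=study.cube.values[:, perm, :],
            features=study.cube.features,
            individuals=study.cube.individuals[perm],
            time_points_h=study.cube.time_points_h,
        )
        dm2 = fit_decay_matrix(shuffled)
        assert np.allclose(dm.median_k.to_numpy(), dm2.median_k.to_numpy())


class TestMeanCellularRate:
    def test_constant_per_cell_rna_is_zero(self):
        cells = np.array([1e6, 2e6, 4e6])
        yields = cells * 20e-3
        rate = estimate_mean_cellular_rate(cells, yields, [0.0, 1.0, 2.0])
        assert rate.lambda_bar == pytest.approx(0.0, abs=1e-12)

    def test_halving_per_hour_is_one(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        cells = np.full(4, 1e6)
        yields = 20.0 * 0.5 ** t
        rate = estimate_mean_cellular_rate(cells, yields, t)
        assert rate.lambda_bar == pytest.approx(1.0, abs=1e-12)

    def test_recovers_configured_rate(self, noiseless_study):
        study, truth = noiseless_study
        one = study.design[study.design["individual_id"] == "IND002"]
        rate = estimate_mean_cellular_rate(
            one["cells"], one["rna_yield_ng"], one["time_h"]
        )
        assert rate.lambda_bar == pytest.approx(truth.lambda_bar.iloc[1], abs=1e-10)

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_mean_cellular_rate([1, 1, 0], [1, 1, 1], [0, 1, 2])


class TestAbsoluteRates:
    def _matrix(self, k_values):
        k = pd.DataFrame(k_values, index=["g1"], columns=["i1"])
        zero = k * 0.0
        return DecayMatrix(k=k, se=zero, p=zero + 1.0, b0=zero)

    def test_shift_and_half_life(self):
        dm = self._matrix([[0.0]])
        shifted, hl = to_absolute_rates(dm, MeanCellularRate(lambda_bar=0.3, se=0.0))
        assert shifted.k.iloc[0, 0] == pytest.approx(0.3)
        assert hl.iloc[0, 0] == pytest.approx(1 / 0.3)

    def test_boundary_half_life_undefined(self):
        dm = self._matrix([[-0.3]])
        shifted, hl = to_absolute_rates(dm, MeanCellularRate(lambda_bar=0.3, se=0.0))
        assert shifted.k.iloc[0, 0] == pytest.approx(0.0)
        assert np.isnan(hl.iloc[0, 0])

    def test_roundtrip_recovers_planted_absolute_rates(self, noiseless_study):
        study, truth = noiseless_study
        dm = fit_decay_matrix(study.cube)
        shifted, _ = to_absolute_rates(
            dm, MeanCellularRate(lambda_bar=float(truth.lambda_bar.iloc[0]), se=0.0)
        )
        assert np.allclose(shifted.k.to_numpy(), truth.k_abs.to_numpy(), atol=1e-10)


class TestClassification:
    def _matrix(self, k_rows, p_rows):
        genes = [f"g{i}" for i in range(len(k_rows))]
        inds = [f"i{j}" for j in range(len(k_rows[0]))]
        k = pd.DataFrame(k_rows, index=genes, columns=inds, dtype=float)
        p = pd.DataFrame(p_rows, index=genes, columns=inds, dtype=float)
        return DecayMatrix(k=k, se=k * 0, p=p, b0=k * 0)

    def test_threshold_and_direction_rules(self):
        n = 70
        k_fast = [1.0] * n
        p_60 = [0.01] * 60 + [0.5] * 10          # 60/70 = 0.857 significant
        p_55 = [0.01] * 55 + [0.5] * 15          # 0.786 < 0.8
        k_split = [1.0] * 35 + [-1.0] * 35       # both directions significant
        p_split = [0.01] * 70
        dm = self._matrix([k_fast, k_fast, k_split], [p_60, p_55, p_split])
        out = classify_decay_genes(dm, alpha=0.1, min_frac=0.8)
        assert list(out.labels) == ["fast", "neither", "neither"]

    def test_slow_direction(self):
        dm = self._matrix([[-1.0] * 10], [[0.01] * 10])
        assert classify_decay_genes(dm).labels.iloc[0] == "slow"

    def test_missing_estimates_excluded_from_denominator(self):
        k = [[1.0] * 8 + [np.nan, np.nan]]
        p = [[0.01] * 8 + [np.nan, np.nan]]
        dm = self._matrix(k, p)
        assert classify_decay_genes(dm).labels.iloc[0] == "fast"  # 8/8

    def test_monotone_in_alpha(self, default_study):
        study, _ = default_study
        dm = fit_decay_matrix(study.cube)
        called = [
            set(classify_decay_genes(dm, alpha=a).labels.pipe(lambda s: s[s != "neither"]).index)
            for a in (0.05, 0.1, 0.2)
        ]
        assert called[0] <= called[1] <= called[2]


class TestTypeIError:
    def test_null_fits_reject_at_alpha(self, rng):
        """Empirical type-I rate of the k != 0 t-test at alpha = 0.1."""
        n = 6000
        y = 8.0 + rng.normal(0, 0.2, size=(n, 5))
        from decayqtl._regression import ols_slope

        fit = ols_slope(TIME_POINTS, y)
        rate = (fit.p < 0.1).mean()
        assert rate == pytest.approx(0.1, abs=0.02)


class TestFeatureRankCorrelation:
    def test_perfect_and_inverse(self, rng):
        k = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        rho, _ = feature_rank_correlation(k, k)
        assert rho == pytest.approx(1.0)
        rho_neg, _ = feature_rank_correlation(-k, k)
        assert rho_neg == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        idx = [f"g{i}" for i in range(80)]
        feat = pd.Series(rng.normal(size=80), index=idx)
        k = pd.Series(0.4 * feat.to_numpy() + rng.normal(size=80), index=idx)
        rho, _ = feature_rank_correlation(feat, k)
        oracle = np.corrcoef(stats.rankdata(feat), stats.rankdata(k))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_subset_restriction(self, rng):
        idx = pd.Index([f"g{i}" for i in range(40)])
        feat = pd.Series(rng.normal(size=40), index=idx)
        k = pd.Series(rng.normal(size=40), index=idx)
        rho_sub, _ = feature_rank_correlation(feat, k, subset=idx[:20])
        oracle = stats.spearmanr(feat[:20], k[:20]).statistic
        assert rho_sub == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_errors(self):
        idx = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError):
            feature_rank_correlation(
                pd.Series(1.0, index=idx), pd.Series(np.arange(10.0), index=idx)
            )
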