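"""GLS estimation, isometry tests and model comparison."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from ocellus.pgls import (
    RankError,
    _fit_from_estimates,
    compare_models,
    fit_feature_regressions,
    fit_pgls,
)
from ocellus.pgls import test_isometry as run_isometry_test
from ocellus.synthgen import GeneratorConfig, simulate_dataset, simulate_tree
from ocellus.treekit import bm_covariance


def gauss_jordan_inverse(M):
    """Hand-coded elimination, independent of numpy.linalg solvers."""
    n = len(M)
    A = [list(map(float, row)) + [1.0 if i == j else 0.0 for j in range(n)]
         for i, row in enumerate(M)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(A[r][col]))
        A[col], A[pivot] = A[pivot], A[col]
        p = A[col][col]
        A[col] = [v / p for v in A[col]]
        for r in range(n):
            if r != col and A[r][col] != 0.0:
                f = A[r][col]
                A[r] = [v - f * w for v, w in zip(A[r], A[col])]
    return np.array([row[n:] for row in A])


class TestFitPgls:
    def test_exact_identity_mapping(self, toy_tree):
        cov = bm_covariance(toy_tree, ridge=0)
        x = np.array([1.0, 2.0, 3.0])
        fit = fit_pgls(x, x, cov)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_identity_covariance_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            y = 2.0 + 0.5 * x + rng.normal(size=n)
            fit = fit_pgls(x, y, np.eye(n))
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
            assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
            assert fit.se_intercept == pytest.approx(ols.bse[0], abs=1e-10)
            assert fit.se_slope == pytest.approx(ols.bse[1], abs=1e-10)

    def test_four_point_explicit_matrix_oracle(self):
        tree = simulate_tree(4, np.random.default_rng(3))
        cov = bm_covariance(tree, ridge=1e-8)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        fit = fit_pgls(x, y, cov)
        # oracle: form V^-1 explicitly by elimination, solve the normal
        # equations by hand
        Vi = gauss_jordan_inverse(cov.matrix)
        X = np.column_stack([np.ones(4), x])
        A = gauss_jordan_inverse(X.T @ Vi @ X)
        beta = A @ X.T @ Vi @ y
        resid = y - X @ beta
        sigma2 = float(resid @ Vi @ resid) / 2
        se = np.sqrt(np.diag(sigma2 * A))
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)
        assert fit.se_intercept == pytest.approx(se[0], rel=1e-9)
        assert fit.se_slope == pytest.approx(se[1], rel=1e-9)

    def test_reordering_rows_leaves_estimates_invariant(self, rng):
        tree = simulate_tree(12, rng)
        cov = bm_covariance(tree, ridge=1e-8)
        n = 12
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        fit = fit_pgls(x, y, cov)
        perm = rng.permutation(n)
        fit_p = fit_pgls(x[perm], y[perm], cov.matrix[np.ix_(perm, perm)])
        assert fit_p.slope == pytest.approx(fit.slope, rel=1e-9)
        assert fit_p.intercept == pytest.approx(fit.intercept, rel=1e-9)
        assert fit_p.sigma2 == pytest.approx(fit.sigma2, rel=1e-9)

    def test_constant_predictor_is_rank_error(self, toy_tree):
        cov = bm_covariance(toy_tree, ridge=0)
        with pytest.raises(RankError):
            fit_pgls(np.ones(3), np.array([1.0, 2.0, 3.0]), cov)

    def test_dimension_mismatch_raises(self, toy_tree):
        cov = bm_covariance(toy_tree, ridge=0)
        with pytest.raises(ValueError):
            fit_pgls(np.arange(4.0), np.arange(4.0), cov)

    def test_parameter_recovery_under_brownian_residuals(self):
        # data simulated under the assumed model: mean estimates over many
        # replicates stay within two Monte-Carlo SEs of the truth
        tree = simulate_tree(20, np.random.default_rng(9))
        cov = bm_covariance(tree, ridge=0)
        L = np.linalg.cholesky(cov.matrix)
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 10, size=20)
        truth_b, truth_s, sigma = 1.5, 0.7, 0.4
        slopes, intercepts = [], []
        for _ in range(500):
            y = truth_b + truth_s * x + sigma * (L @ rng.normal(size=20))
            fit = fit_pgls(x, y, cov)
            slopes.append(fit.slope)
            intercepts.append(fit.intercept)
        for values, truth in ((slopes, truth_s), (intercepts, truth_b)):
            mc_se = np.std(values, ddof=1) / math.sqrt(len(values))
            assert abs(np.mean(values) - truth) < 2 * mc_se + 1e-12


class TestIsometry:
    def _fit(self, slope, se_slope, intercept=0.0, se_intercept=1.0, df=100):
        cov_beta = np.diag([se_intercept**2, se_slope**2])
        return _fit_from_estimates(
            np.array([intercept, slope]), cov_beta, 1.0, df + 2
        )

    def test_slope_exactly_one_gives_p_one(self):
        t = run_isometry_test(self._fit(1.0, 0.3))
        assert t.p_slope_eq_1 == pytest.approx(1.0)
        assert not t.slope_differs_from_1

    def test_intercept_zero_gives_p_one(self):
        t = run_isometry_test(self._fit(2.0, 0.3, intercept=0.0))
        assert t.p_intercept_eq_0 == pytest.approx(1.0)

    def test_p_value_matches_quadrature_oracle(self):
        # independent oracle: numerically integrate the t density
        fit = self._fit(1.5, 0.1, df=100)
        df = 100
        const = special.gamma((df + 1) / 2) / (
            math.sqrt(df * math.pi) * special.gamma(df / 2)
        )
        density = lambda u: const * (1 + u * u / df) ** (-(df + 1) / 2)
        t_obs = (1.5 - 1.0) / 0.1
        tail, _ = integrate.quad(density, t_obs, np.inf)
        assert run_isometry_test(fit).p_slope_eq_1 == pytest.approx(2 * tail, rel=1e-8)


class TestCompareModels:
    def _fit(self, slope, intercept, se=0.1):
        return _fit_from_estimates(
            np.array([intercept, slope]), np.diag([se**2, se**2]), 1.0, 50
        )

    def test_identical_fits_do_not_differ(self):
        f = self._fit(1.0, 0.0)
        cmp = compare_models(f, f)
        assert not cmp.slopes_differ and not cmp.intercepts_differ

    def test_disjoint_intercept_intervals_differ(self):
        cmp = compare_models(self._fit(1.0, 1.0), self._fit(1.0, 2.5))
        assert cmp.intercepts_differ and not cmp.slopes_differ

    def test_equal_slopes_offset_intercepts_detected_on_synthetic_data(self):
        # the eye/eyespot and pupil/eyespot-pupil models share a slope of
        # one but only the pupil model has a positive offset
        hits = 0
        for seed in range(20):
            cfg = GeneratorConfig(seed=300 + seed, n_species=60)
            tree = simulate_tree(cfg.n_species, np.random.default_rng(cfg.seed))
            ds, _ = simulate_dataset(tree, cfg)
            fits, _ = fit_feature_regressions(
                ds, tree, models=["eye_area", "pupil_area"]
            )
            cmp = compare_models(fits["eye_area"], fits["pupil_area"])
            hits += (not cmp.slopes_differ) and cmp.intercepts_differ
        assert hits >= 18


class TestFeatureRegressions:
    def test_coefficient_table_has_eight_rows(self):
        cfg = GeneratorConfig(seed=2, n_species=40)
        tree = simulate_tree(cfg.n_species, np.random.default_rng(cfg.seed))
        ds, _ = simulate_dataset(tree, cfg)
        fits, table = fit_feature_regressions(ds, tree)
        assert len(table) == 8
        assert set(table["model"]) == {
            "eye_area", "pupil_area", "eye_diameter", "pupil_diameter"
        }

    def test_species_missing_from_tree_is_named_error(self):
        cfg = GeneratorConfig(seed=2, n_species=40)
        tree = simulate_tree(cfg.n_species, np.random.default_rng(cfg.seed))
        ds, _ = simulate_dataset(tree, cfg)
        pruned = simulate_tree(cfg.n_species, np.random.default_rng(99))
        relabel = {
            lab: f"other{idx}" for idx, lab in enumerate(pruned.tip_labels)
        }
        for leaf in pruned.tree.leaf_node_iter():
            leaf.taxon.label = relabel[leaf.taxon.label]
        with pytest.raises(KeyError, match="absent from tree"):
            fit_feature_regressions(ds, pruned)

    def test_fixed_ridge_accepted_and_ml_default_sane(self):
        cfg = GeneratorConfig(seed=4, n_species=40)
        tree = simulate_tree(cfg.n_species, np.random.default_rng(cfg.seed))
        ds, _ = simulate_dataset(tree, cfg)
        fits_ml, _ = fit_feature_regressions(ds, tree, models=["eye_area"])
        fits_fx, _ = fit_feature_regressions(
            ds, tree, ridge=1.0, models=["eye_area"]
        )
        for fits in (fits_ml, fits_fx):
            assert 0.8 < fits["eye_area"].slope < 1.2
        with pytest.raises(ValueError):
            fit_feature_regressions(ds, tree, ridge="bogus")
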