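"""Bayesian ridge regression and Savage-Dickey Bayes factors."""

import numpy as np
import pytest

from causalfpr.bayes_test import (
    InsufficientDataError,
    RegressionSpec,
    SingularDesignError,
    bf01,
    check_implication,
    fit_bayes_linreg,
)
from causalfpr.scm import SampleMatrix, collider_model, confounder_model, simulate

from .oracles import quadrature_bf01, textbook_ols


def _sample(n, rng, slope=0.0, extra_cols=0):
    """outcome = slope * regressor + noise, optional unrelated adjusters."""
    x = rng.standard_normal(n)
    y = slope * x + rng.standard_normal(n)
    cols = [y, x] + [rng.standard_normal(n) for _ in range(extra_cols)]
    names = ("Y", "X") + tuple(f"Z{i}" for i in range(extra_cols))
    return SampleMatrix(np.column_stack(cols), names)


class TestSpecValidation:
    def test_rejects_overlapping_roles(self):
        with pytest.raises(ValueError):
            RegressionSpec("Y", "Y")
        with pytest.raises(ValueError):
            RegressionSpec("Y", "X", frozenset({"X"}))
        with pytest.raises(ValueError):
            RegressionSpec("Y", "X", frozenset({"Y"}))


class TestFit:
    def test_noise_free_proportional_column_recovered_exactly(self, rng):
        # outcome is exactly 2x the regressor: residual variance collapses,
        # so the ridge penalty vanishes and the posterior concentrates at 2.
        x = rng.standard_normal(500)
        data = SampleMatrix(np.column_stack([2 * x, x]), ("Y", "X"))
        fit = fit_bayes_linreg(data, RegressionSpec("Y", "X"))
        mean, sd = fit.coefficient("X")
        assert mean == pytest.approx(2.0, abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_flat_prior_limit_recovers_textbook_ols(self, rng):
        data = _sample(200, rng, slope=0.4, extra_cols=1)
        spec = RegressionSpec("Y", "X", frozenset({"Z0"}))
        fit = fit_bayes_linreg(data, spec, prior_sd=1e8)
        ols = textbook_ols(
            data.column("Y"), np.column_stack([data.column(n) for n in fit.names])
        )
        np.testing.assert_allclose(fit.mean, ols, atol=1e-8)

    def test_flat_prior_limit_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        data = _sample(150, rng, slope=-0.7, extra_cols=2)
        spec = RegressionSpec("Y", "X", frozenset({"Z0", "Z1"}))
        fit = fit_bayes_linreg(data, spec, prior_sd=1e8)
        design = sm.add_constant(
            np.column_stack([data.column(n) for n in fit.names])
        )
        ref = sm.OLS(data.column("Y"), design).fit().params[1:]
        np.testing.assert_allclose(fit.mean, ref, atol=1e-8)

    def test_zero_coefficients_estimated_near_zero_at_large_n(self, rng):
        data = _sample(10**5, rng, slope=0.0, extra_cols=2)
        spec = RegressionSpec("Y", "X", frozenset({"Z0", "Z1"}))
        fit = fit_bayes_linreg(data, spec)
        assert np.all(np.abs(fit.mean) < 0.02)

    def test_single_regressor_posterior_mean_shrinks_toward_zero(self, rng):
        for _ in range(20):
            data = _sample(30, rng, slope=rng.uniform(-2, 2))
            fit = fit_bayes_linreg(data, RegressionSpec("Y", "X"), prior_sd=0.7)
            assert abs(fit.mean[0]) <= abs(fit.ols[0]) + 1e-14

    def test_multiregressor_norm_shrinkage(self, rng):
        m = confounder_model(0.3, 0.8, 0.5)
        for seed in range(10):
            data = simulate(m, 40, seed=seed)
            fit = fit_bayes_linreg(
                data, RegressionSpec("Y", "X", frozenset({"C"})), prior_sd=0.5
            )
            assert np.linalg.norm(fit.mean) <= np.linalg.norm(fit.ols) + 1e-14

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(50)
        data = SampleMatrix(
            np.column_stack([rng.standard_normal(50), x, 3 * x]), ("Y", "X", "Z0")
        )
        with pytest.raises(SingularDesignError):
            fit_bayes_linreg(data, RegressionSpec("Y", "X", frozenset({"Z0"})))

    def test_too_few_rows_raises(self, rng):
        data = _sample(3, rng, extra_cols=1)
        with pytest.raises(InsufficientDataError):
            fit_bayes_linreg(data, RegressionSpec("Y", "X", frozenset({"Z0"})))


class TestBf01:
    def test_matches_quadrature_marginal_likelihood_ratio(self, rng):
        """Savage-Dickey closed form vs numerical marginal likelihoods."""
        for i in range(20):
            slope = [0.0, 0.3, -0.8, 1.5][i % 4]
            k = i % 2  # without / with one adjustment column
            data = _sample(12 + i, rng, slope=slope, extra_cols=k)
            adjustment = frozenset(f"Z{j}" for j in range(k))
            spec = RegressionSpec("Y", "X", adjustment)
            ours = bf01(data, spec).bf01
            x = data.column("X")
            z = (
                np.column_stack([data.column(c) for c in sorted(adjustment)])
                if k
                else np.empty((data.n, 0))
            )
            oracle = quadrature_bf01(data.column("Y"), x, z)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_median_bf01_favors_null_under_null(self, rng):
        bfs = [bf01(_sample(100, rng, 0.0), RegressionSpec("Y", "X")).bf01
               for _ in range(300)]
        assert np.median(bfs) > 1

    def test_strong_effect_rejects_null(self, rng):
        hits = sum(
            bf01(_sample(100, rng, 0.9), RegressionSpec("Y", "X")).bf01 < 1
            for _ in range(200)
        )
        assert hits / 200 > 0.95

    def test_bf01_increases_with_n_under_null(self, rng):
        med = {}
        for n in (20, 200):
            med[n] = np.median(
                [bf01(_sample(n, rng, 0.0), RegressionSpec("Y", "X")).bf01
                 for _ in range(300)]
            )
        assert med[200] > med[20]

    def test_row_permutation_invariance(self, rng):
        data = _sample(60, rng, slope=0.5, extra_cols=1)
        spec = RegressionSpec("Y", "X", frozenset({"Z0"}))
        perm = rng.permutation(60)
        shuffled = SampleMatrix(data.values[perm], data.columns)
        assert bf01(data, spec).bf01 == pytest.approx(bf01(shuffled, spec).bf01)

    def test_cache_shares_fit_across_coefficients(self, rng):
        m = collider_model(0.5, 0.5, 0.5)
        data = simulate(m, 200, seed=8)
        cache = {}
        bf01(data, RegressionSpec("Y", "X", frozenset({"C"})), 1.0, cache)
        bf01(data, RegressionSpec("Y", "C", frozenset({"X"})), 1.0, cache)
        assert len(cache) == 1  # same full model Y ~ X + C


class TestCheckImplication:
    def test_true_zero_implication_holds_at_large_n(self):
        data = simulate(collider_model(0.5, 0.5, 0.5), 10**5, seed=21)
        violated, detail = check_implication(
            data, RegressionSpec("Y", "X", frozenset({"C"})), "zero"
        )
        assert not violated and detail.bf01 > 1

    def test_true_nonzero_implication_holds_at_large_n(self):
        data = simulate(confounder_model(0.25, 0.9, 0.25), 10**5, seed=22)
        violated, detail = check_implication(
            data, RegressionSpec("X", "C"), "nonzero"
        )
        assert not violated and detail.bf01 < 1

    def test_zero_and_nonzero_never_both_violated(self, rng):
        for _ in range(50):
            data = _sample(40, rng, slope=rng.uniform(-1, 1))
            spec = RegressionSpec("Y", "X")
            v0, _ = check_implication(data, spec, "zero")
            v1, _ = check_implication(data, spec, "nonzero")
            assert not (v0 and v1)

    def test_invalid_expectation_rejected(self, rng):
        with pytest.raises(ValueError):
            check_implication(_sample(20, rng), RegressionSpec("Y", "X"), "maybe")
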