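"""Delta-method SEs, genetic correlations, Wald/LRT, AIC/BIC, reduction."""

import numpy as np
import pytest

from gsemkit import (aic, bic, cholesky_spec, common_pathway_spec,
                     compare_models, custom_spec, delta_method_se,
                     drop_loading, fit, genetic_correlations,
                     genetic_variance_share, implied_covariances, lrt,
                     reduce_model, simulate_phenotypes_from_grm, wald_test)
from gsemkit.fiml import FitResult
from gsemkit.inference import _genetic_candidates, _pick_drop


def make_result(spec, theta, param_cov=None, minus2LL=1000.0, n=500,
                converged=True):
    theta = np.asarray(theta, float)
    if param_cov is None:
        param_cov = np.eye(spec.k) * 0.01
    return FitResult(spec=spec, theta_hat=theta, minus2LL=minus2LL,
                     param_cov=param_cov, se_theta=np.sqrt(np.diag(param_cov)),
                     converged=converged, n_samples=n, n_observations=n * spec.t)


class TestDeltaMethod:
    def test_identity_function_reproduces_se(self):
        spec = cholesky_spec(1)
        res = make_result(spec, [0.5, 0.8],
                          param_cov=np.diag([0.04, 0.09]))
        val, se = delta_method_se(res, lambda th: th[0])
        assert val == pytest.approx(0.5)
        assert se == pytest.approx(res.se_theta[0], rel=1e-6)

    def test_square_closed_form(self):
        # g = a^2: SE = 2 |a| sqrt(var(a))
        a, v = 0.6, 0.04
        res = make_result(cholesky_spec(1), [a, 1.0], param_cov=np.diag([v, 0.01]))
        val, se = delta_method_se(res, lambda th: th[0] ** 2)
        assert val == pytest.approx(a ** 2)
        assert se == pytest.approx(2 * a * np.sqrt(v), rel=1e-4)

    def test_missing_covariance_rejected(self):
        res = make_result(cholesky_spec(1), [0.5, 0.8])
        res.param_cov = None
        with pytest.raises(ValueError, match="covariance unavailable"):
            delta_method_se(res, lambda th: th[0])

    def test_parametric_bootstrap_agreement_for_rg(self):
        # parametric-bootstrap oracle: simulate from the fitted model, refit,
        # and compare the spread of r_g draws with the delta-method SE
        from conftest import grm_from_random
        from gsemkit import eigendecompose_grm

        rng = np.random.default_rng(91)
        grm = grm_from_random(rng, 600, 700)
        eig = eigendecompose_grm(grm)
        sigma_g = np.array([[0.35, 0.20], [0.20, 0.45]])
        sigma_e = np.array([[0.65, 0.15], [0.15, 0.55]])
        Y = simulate_phenotypes_from_grm(grm, sigma_g, sigma_e, seed=42)
        res = fit(cholesky_spec(2), Y, eig, seed=42)
        der = genetic_correlations(res)
        sg_hat = implied_covariances(res.spec, res.theta_hat).sigma_g
        se_hat = implied_covariances(res.spec, res.theta_hat).sigma_e
        rgs = []
        for b in range(120):
            Yb = simulate_phenotypes_from_grm(grm, sg_hat, se_hat, seed=1000 + b)
            rb = fit(cholesky_spec(2), Yb, eig, seed=b, n_starts=1,
                     compute_se=False)
            sg = implied_covariances(rb.spec, rb.theta_hat).sigma_g
            if sg[0, 0] > 1e-6 and sg[1, 1] > 1e-6:
                rgs.append(sg[1, 0] / np.sqrt(sg[0, 0] * sg[1, 1]))
        boot_se = np.std(rgs)
        assert der.r_g_se[1, 0] == pytest.approx(boot_se, rel=0.15)


class TestGeneticCorrelations:
    def test_rank_one_gives_unit_correlation(self):
        spec = cholesky_spec(2)
        theta = np.array([0.6, 0.4, 0.0, 0.8, 0.1, 0.7])  # a22 = 0 -> rank-1
        der = genetic_correlations(make_result(spec, theta))
        assert abs(der.r_g[1, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_sigma_gives_zero(self):
        spec = custom_spec(np.eye(2, dtype=bool), np.tril(np.ones((2, 2), bool)))
        theta = np.array([0.5, 0.6, 0.8, 0.1, 0.7])
        der = genetic_correlations(make_result(spec, theta))
        assert der.r_g[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        spec = cholesky_spec(3)
        theta = rng.normal(size=spec.k) + 0.5
        res = make_result(spec, theta)
        der = genetic_correlations(res)
        sg = implied_covariances(spec, theta).sigma_g
        for i in range(3):
            for j in range(3):
                expected = sg[i, j] / np.sqrt(sg[i, i] * sg[j, j])
                assert der.r_g[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.all(np.abs(der.r_g) <= 1 + 1e-8)
        np.testing.assert_allclose(np.diag(der.r_g), 1.0)

    def test_zero_genetic_variance_warns(self):
        spec = cholesky_spec(2)
        theta = np.array([0.6, 0.4, 0.5, 0.8, 0.1, 0.7])
        theta[[0]] = 0.0
        theta[[1]] = 0.0  # trait-1 genetic variance exactly zero
        with pytest.warns(UserWarning, match="undefined"):
            der = genetic_correlations(make_result(spec, theta))
        assert np.isnan(der.r_g[1, 0])

    def test_variance_share_of_leading_factor(self):
        spec = cholesky_spec(2)
        theta = np.array([0.6, 0.3, 0.4, 0.8, 0.1, 0.7])
        res = make_result(spec, theta)
        share, se = genetic_variance_share(res, trait=1, factors=[0])
        assert share == pytest.approx(0.3 ** 2 / (0.3 ** 2 + 0.4 ** 2))
        assert se > 0


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        res = make_result(cholesky_spec(1), [0.0, 1.0])
        z, p = wald_test(res, "a11")
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_z_1p96_gives_p05(self):
        res = make_result(cholesky_spec(1), [1.96 * 0.1, 1.0],
                          param_cov=np.diag([0.01, 0.01]))
        _, p = wald_test(res, "a11")
        assert p == pytest.approx(0.05, abs=0.001)

    def test_one_tailed_halves(self):
        res = make_result(cholesky_spec(1), [0.15, 1.0])
        _, p2 = wald_test(res, "a11")
        _, p1 = wald_test(res, "a11", one_tailed=True)
        assert p1 == pytest.approx(p2 / 2)

    def test_missing_se_rejected(self):
        res = make_result(cholesky_spec(1), [0.5, 1.0])
        res.se_theta = np.array([np.nan, 0.1])
        with pytest.raises(ValueError, match="unavailable"):
            wald_test(res, "a11")


class TestLRT:
    def _fits(self):
        full_spec = cholesky_spec(4)
        two = full_spec
        for nm in ("a33", "a43", "a44"):
            two = drop_loading(two, nm)
        f_full = make_result(full_spec, np.zeros(20), minus2LL=7900.97, n=3295)
        f_two = make_result(two, np.zeros(17), minus2LL=7900.98, n=3295)
        return f_full, f_two

    def test_full_vs_two_factor_df(self):
        f_full, f_two = self._fits()
        cmp_ = lrt(f_full, f_two)
        assert cmp_.delta_df == 3
        assert cmp_.p_value == pytest.approx(1.0, abs=0.01)

    def test_pathway_model_dfs(self):
        from gsemkit import independent_pathway_spec
        f_full = make_result(cholesky_spec(4), np.zeros(20), minus2LL=7900.97, n=3295)
        f_ip = make_result(independent_pathway_spec(4), np.zeros(16),
                           minus2LL=7914.51, n=3295)
        f_cp = make_result(common_pathway_spec(4), np.zeros(14),
                           minus2LL=8082.71, n=3295)
        assert lrt(f_full, f_ip).delta_df == 4
        assert lrt(f_full, f_cp).delta_df == 6
        assert lrt(f_full, f_ip).delta_chi2 == pytest.approx(13.54)

    def test_identical_specs_rejected(self):
        f_full, _ = self._fits()
        with pytest.raises(ValueError, match="nested"):
            lrt(f_full, f_full)

    def test_small_negative_chi2_clamped(self):
        f_full, f_two = self._fits()
        f_two.minus2LL = f_full.minus2LL - 5e-5
        assert lrt(f_full, f_two).delta_chi2 == 0.0
        f_two.minus2LL = f_full.minus2LL - 1.0
        with pytest.raises(ValueError, match="fits better"):
            lrt(f_full, f_two)

    def test_different_samples_rejected(self):
        f_full, f_two = self._fits()
        f_two.n_samples = 100
        with pytest.raises(ValueError, match="same samples"):
            lrt(f_full, f_two)

    def test_mixture_reference_smaller_p(self):
        f_full, f_two = self._fits()
        f_two.minus2LL = f_full.minus2LL + 6.0
        assert lrt(f_full, f_two, mixture=True).p_value < lrt(f_full, f_two).p_value


class TestInformationCriteria:
    def test_bookkeeping_from_printed_inputs(self):
        # -2LL = 7900.97, k = 20, n = 3295 participants
        assert aic(7900.97, 20) == pytest.approx(7940.97)
        assert bic(7900.97, 20, 3295) == pytest.approx(8062.97, abs=0.005)

    def test_zero_parameters(self):
        assert aic(123.4, 0) == 123.4
        assert bic(123.4, 0, 50) == 123.4

    def test_bic_needs_participants(self):
        with pytest.raises(ValueError):
            bic(100.0, 2, 1)

    def test_comparison_table(self):
        f_full = make_result(cholesky_spec(4), np.zeros(20), minus2LL=7900.97, n=3295)
        two = cholesky_spec(4)
        for nm in ("a33", "a43", "a44"):
            two = drop_loading(two, nm)
        f_two = make_result(two, np.zeros(17), minus2LL=7900.98, n=3295)
        table = compare_models({"full": f_full, "two_factor": f_two})
        assert table.loc["full", "AIC"] == pytest.approx(7940.97)
        assert table.loc["full", "BIC"] == pytest.approx(8062.97, abs=0.005)
        assert table.loc["two_factor", "delta_df"] == 3
        assert table.loc["two_factor", "k"] == 17


class TestReduction:
    def test_tie_break_drops_later_position(self):
        spec = cholesky_spec(2)
        # a21 and a22 have identical standardized size; a22 sits on the later
        # factor, so it is the one to drop
        theta = np.array([1.0, 0.3, 0.3, 1.0, 0.0, 1.0])
        res = make_result(spec, theta)
        cands = _genetic_candidates(res)
        name, _ = _pick_drop(res, cands)
        assert name == "a22"

    def test_recovers_two_factor_structure(self, medium_grm):
        # truth: 4 traits, exactly 2 genetic factors, strong loadings
        La = np.array([[0.60, 0.00], [0.50, 0.45], [0.45, 0.40], [0.40, 0.55]])
        sigma_g = La @ La.T
        sigma_e = 0.45 * np.eye(4) + 0.10
        spec4 = cholesky_spec(4)
        kept_counts = []
        for seed in (11, 12):
            Y = simulate_phenotypes_from_grm(medium_grm, sigma_g, sigma_e, seed=seed)
            start = fit(spec4, Y, medium_grm, seed=seed)
            red = reduce_model(start, Y, medium_grm, alpha=0.05, seed=seed)
            La_fit, _ = red.final.spec.loadings(np.ones(red.final.spec.k))
            n_factors = int((np.abs(La_fit).sum(axis=0) > 0).sum())
            kept_counts.append(n_factors)
        assert min(kept_counts) >= 2 and max(kept_counts) <= 3
        assert 2 in kept_counts

    def test_no_drops_when_all_loadings_strong(self, medium_grm):
        La = np.array([[0.7, 0.0], [0.45, 0.55]])
        sigma_g = La @ La.T
        sigma_e = np.array([[0.45, 0.1], [0.1, 0.4]])
        Y = simulate_phenotypes_from_grm(medium_grm, sigma_g, sigma_e, seed=21)
        start = fit(cholesky_spec(2), Y, medium_grm, seed=21)
        red = reduce_model(start, Y, medium_grm, alpha=0.05, seed=21)
        assert red.steps == []
        assert red.stopped_because == "all genetic loadings significant"

    def test_requires_converged_start(self):
        res = make_result(cholesky_spec(2), np.zeros(6), converged=False)
        with pytest.raises(ValueError, match="converged"):
            reduce_model(res, None, None)
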