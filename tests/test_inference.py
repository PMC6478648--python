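import numpy as np
import pytest
from scipy.special import expit

from hmmixrt import (ModelSpec, build_grid, fit, marginal_loglik, npar_of,
                     standard_errors, to_unconstrained, validate_dataset)
from hmmixrt.core import relabel_states
from hmmixrt.inference import FitOptions, observed_information
from hmmixrt.selection import simulate_categorized

from _oracles import dense_marginal_loglik
from conftest import random_params


class TestQuadrature:
    def test_zero_correlation_is_product_grid(self):
        g = build_grid(0.0, 6)
        z = np.unique(np.round(g.nodes[:, 0], 12))
        assert z.size == 6
        assert np.allclose(np.sort(np.unique(np.round(g.nodes[:, 1], 12))), z)

    def test_weights_normalized(self):
        g = build_grid(0.3, 10)
        assert abs(g.weights.sum() - 1.0) < 1e-12

    def test_cross_moment_equals_rho(self):
        for rho in (-0.6, 0.0, 0.4, 0.85):
            g = build_grid(rho, 10)
            m = np.sum(g.weights * g.nodes[:, 0] * g.nodes[:, 1])
            assert m == pytest.approx(rho, abs=1e-8)
            assert np.sum(g.weights * g.nodes[:, 1] ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_grid(1.0)
        with pytest.raises(ValueError):
            build_grid(0.0, 1)


class TestMarginalLoglik:
    def _tiny(self, variant, n, T, N, seed):
        spec = ModelSpec(variant, n, T)
        rng = np.random.default_rng(seed)
        params = random_params(spec, rng)
        resp = rng.integers(0, 2, (N, n)).astype(float)
        rts = rng.integers(0, T, (N, n)).astype(float)
        return spec, params, resp, rts

    def test_missing_response_single_item_matches_dense_oracle(self):
        spec, params, _, rts = self._tiny("baseline", 1, 2, 3, 1)
        resp = np.full((3, 1), np.nan)
        data = validate_dataset(resp, rts, 2)
        got = marginal_loglik(data, params, spec, grid=build_grid(params.rho, 40))
        want = dense_marginal_loglik(data.responses, data.rt_categories, params, spec)
        assert got == pytest.approx(want, abs=1e-6)

    def test_fully_missing_person_contributes_zero(self):
        spec, params, resp, rts = self._tiny("hetero_markov", 3, 2, 4, 2)
        data = validate_dataset(resp, rts, 2)
        base = marginal_loglik(data, params, spec)
        resp2, rts2 = resp.copy(), rts.copy()
        resp2[0], rts2[0] = np.nan, np.nan
        reduced = marginal_loglik(validate_dataset(resp2, rts2, 2), params, spec)
        one_person = marginal_loglik(validate_dataset(resp[:1], rts[:1], 2), params, spec)
        assert reduced == pytest.approx(base - one_person, abs=1e-8)

    def test_hetero_with_unit_scale_equals_homo(self):
        spec_h, params, resp, rts = self._tiny("hetero_markov", 3, 3, 5, 3)
        params.sigma1 = 1.0
        spec_o = ModelSpec("homo_markov", 3, 3)
        params_o = params.copy()
        params_o.sigma1 = None
        data = validate_dataset(resp, rts, 3)
        assert (marginal_loglik(data, params, spec_h)
                == pytest.approx(marginal_loglik(data, params_o, spec_o), abs=1e-10))

    @pytest.mark.parametrize("variant", ["baseline", "hetero_markov", "homo_indep"])
    def test_matches_dense_oracle(self, variant):
        spec, params, resp, rts = self._tiny(variant, 4, 2, 5, 4)
        resp[0, 1] = np.nan
        rts[2, 0] = np.nan
        data = validate_dataset(resp, rts, 2)
        got = marginal_loglik(data, params, spec, grid=build_grid(params.rho, 40))
        want = dense_marginal_loglik(data.responses, data.rt_categories, params, spec)
        assert got == pytest.approx(want, abs=1e-5)

    def test_category_range_checked(self):
        spec, params, resp, rts = self._tiny("baseline", 2, 3, 3, 5)
        data = validate_dataset(resp, rts, 3)
        with pytest.raises(ValueError, match="outside"):
            marginal_loglik(data, params, ModelSpec("baseline", 2, 2))


class TestFit:
    def test_em_trace_monotone(self, small_hetero):
        data, *_ = small_hetero
        spec = ModelSpec("hetero_markov", 8, 3)
        res = fit(data, spec, FitOptions(refine=False, em_max_iter=60, em_tol=1e-8))
        assert np.all(np.diff(res.trace) >= -1e-8)

    def test_baseline_item_recovery_within_three_se(self):
        data, truth, *_ = simulate_categorized("baseline", N=1000, n=20, T=5, seed=5150)
        spec = ModelSpec("baseline", 20, 5)
        res = fit(data, spec, FitOptions(seed=0))
        assert res.converged
        ses = standard_errors(res, data)
        ok_alpha = np.abs(res.estimates.alpha0 - truth.alpha0) <= 3 * ses.alpha0
        ok_beta = np.abs(res.estimates.beta0 - truth.beta0) <= 3 * ses.beta0
        assert ok_alpha.mean() >= 0.9
        assert ok_beta.mean() >= 0.9

    def test_nesting_of_maximized_likelihoods(self, small_hetero):
        data, *_ = small_hetero
        lls = {}
        for variant in ("hetero_markov", "homo_markov", "hetero_indep", "homo_indep",
                        "baseline"):
            spec = ModelSpec(variant, 8, 3)
            lls[variant] = fit(data, spec, FitOptions(seed=1)).loglik
        for variant in ("homo_markov", "hetero_indep", "homo_indep", "baseline"):
            assert lls["hetero_markov"] >= lls[variant] - 1e-4

    def test_label_relabeling_preserves_likelihood_and_anchor(self, small_hetero,
                                                              small_hetero_fit):
        data, *_ = small_hetero
        spec = small_hetero_fit.spec
        est = small_hetero_fit.estimates
        assert est.delta1 > 0  # anchor applied
        swapped = relabel_states(est, spec)
        ll_orig = marginal_loglik(data, est, spec)
        ll_swap = marginal_loglik(data, swapped, spec)
        assert ll_swap == pytest.approx(ll_orig, abs=1e-8)
        # refitting from the swapped start lands on the same anchored optimum
        res2 = fit(data, spec, FitOptions(start_params=swapped, seed=2))
        assert res2.loglik == pytest.approx(small_hetero_fit.loglik, abs=5e-3)
        assert res2.estimates.delta1 > 0
        assert res2.estimates.pi1 == pytest.approx(est.pi1, abs=0.02)

    def test_npar_reported(self, small_hetero_fit):
        assert small_hetero_fit.npar == npar_of(small_hetero_fit.spec)


class TestStandardErrors:
    def test_logistic_subproblem_matches_fisher_information(self):
        # Bernoulli(expit(b)) log-likelihood: closed-form information N*p*(1-p)
        rng = np.random.default_rng(8)
        N, b_true = 4000, 0.4
        x = (rng.random(N) < expit(b_true)).astype(float)

        def per_person(u):
            return x * np.log(expit(u[0])) + (1 - x) * np.log(1 - expit(u[0]))

        b_hat = np.log(x.mean() / (1 - x.mean()))
        p_hat = expit(b_hat)
        for method in ("opg", "hessian"):
            info = observed_information(per_person, np.array([b_hat]), method=method)
            assert info[0, 0] == pytest.approx(N * p_hat * (1 - p_hat), rel=0.02)

    def test_se_shrinks_with_sample_size(self):
        ses = {}
        for N in (250, 500):
            data, *_ = simulate_categorized("hetero_markov", N=N, n=6, T=3, seed=77)
            spec = ModelSpec("hetero_markov", 6, 3)
            res = fit(data, spec, FitOptions(seed=0))
            ses[N] = standard_errors(res, data).pi1_given1
        assert 0.5 <= ses[500] / ses[250] <= 0.95

    def test_opg_and_hessian_agree_on_small_model(self):
        data, *_ = simulate_categorized("baseline", N=400, n=3, T=2, seed=9)
        spec = ModelSpec("baseline", 3, 2)
        res = fit(data, spec, FitOptions(seed=0))
        se_opg = standard_errors(res, data, method="opg")
        se_hes = standard_errors(res, data, method="hessian")
        assert np.allclose(se_opg.beta0, se_hes.beta0, rtol=0.25)
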