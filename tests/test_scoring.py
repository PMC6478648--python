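import numpy as np
import pytest

from hmmixrt import (FitResult, ModelSpec, eap_scores, fit, npar_of, standardized_rts,
                     state_posteriors, validate_dataset)
from hmmixrt.categorize import categorize_matrix, normal_quantile_percentiles
from hmmixrt.inference import FitOptions
from hmmixrt.markov import chain_from_params
from hmmixrt.selection import simulate_categorized
from hmmixrt.simulate import scenario_defaults, simulate_continuous

from conftest import random_params


def _fake_fit(spec, params):
    return FitResult(spec=spec, estimates=params, loglik=0.0, npar=npar_of(spec),
                     converged=True)


class TestEapScores:
    def test_all_missing_person_gets_prior(self, small_hetero, small_hetero_fit):
        data, *_ = small_hetero
        resp = data.responses.astype(float)
        rts = data.rt_categories.astype(float)
        resp[resp < 0] = np.nan
        rts[rts < 0] = np.nan
        resp[0], rts[0] = np.nan, np.nan
        blanked = validate_dataset(resp, rts, data.n_categories)
        eap = eap_scores(blanked, small_hetero_fit)
        assert eap["theta"][0] == pytest.approx(0.0, abs=1e-8)
        assert eap["tau"][0] == pytest.approx(0.0, abs=1e-8)
        assert eap["sd_theta"][0] == pytest.approx(1.0, abs=1e-6)
        assert eap["sd_tau"][0] == pytest.approx(1.0, abs=1e-6)

    def test_all_correct_scores_above_all_incorrect(self, small_hetero_fit):
        n = small_hetero_fit.spec.n_items
        resp = np.vstack([np.ones(n), np.zeros(n)])
        rts = np.ones((2, n))
        data = validate_dataset(resp, rts, small_hetero_fit.spec.n_categories)
        eap = eap_scores(data, small_hetero_fit)
        assert eap["theta"][0] > eap["theta"][1]

    def test_item_order_invariance_for_independent_states(self):
        spec = ModelSpec("hetero_indep", 6, 3)
        rng = np.random.default_rng(3)
        params = random_params(spec, rng)
        resp = rng.integers(0, 2, (40, 6)).astype(float)
        rts = rng.integers(0, 3, (40, 6)).astype(float)
        data = validate_dataset(resp, rts, 3)
        perm = rng.permutation(6)
        params_p = params.copy()
        for name in ("alpha0", "alpha1", "beta0", "beta1", "lam"):
            setattr(params_p, name, getattr(params, name)[perm])
        params_p.nu = params.nu[perm]
        data_p = validate_dataset(resp[:, perm], rts[:, perm], 3)
        a = eap_scores(data, _fake_fit(spec, params))
        b = eap_scores(data_p, _fake_fit(spec, params_p))
        assert np.allclose(a["theta"], b["theta"], atol=1e-10)
        assert np.allclose(a["tau"], b["tau"], atol=1e-10)

    def test_cross_category_count_agreement(self):
        """EAPs from T=2 and T=5 categorizations of the same data agree strongly."""
        truth = scenario_defaults("hetero_markov", N=500, n=14)
        responses, raw_times, _states, _lat = simulate_continuous(truth, seed=404)
        taus = {}
        for T in (2, 5):
            cats = categorize_matrix(raw_times, normal_quantile_percentiles(T))
            data = validate_dataset(responses.astype(float), cats, T)
            res = fit(data, ModelSpec("hetero_markov", 14, T), FitOptions(seed=0))
            taus[T] = eap_scores(data, res)["tau"]
        corr = np.corrcoef(taus[2], taus[5])[0, 1]
        assert corr > 0.9


class TestStatePosteriors:
    def test_sum_to_one(self, small_hetero, small_hetero_fit):
        data, *_ = small_hetero
        post = state_posteriors(data, small_hetero_fit)
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-12)

    def test_baseline_fit_rejected(self):
        spec = ModelSpec("baseline", 3, 2)
        params = random_params(spec, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        data = validate_dataset(rng.integers(0, 2, (5, 3)).astype(float),
                                rng.integers(0, 2, (5, 3)).astype(float), 2)
        with pytest.raises(ValueError, match="no latent states"):
            state_posteriors(data, _fake_fit(spec, params))

    def test_dominant_evidence_from_large_shift(self):
        spec = ModelSpec("hetero_markov", 4, 3)
        params = random_params(spec, np.random.default_rng(7))
        params.delta1, params.sigma1 = 6.0, 1.0
        # category 0 is rare in the slow state but dominant in the fast one
        params.nu = np.tile([2.0, 2.0], (4, 1))
        params.lam = np.full(4, 0.3)
        # neutral chain so only the RT evidence drives the posterior
        params.pi1, params.pi1_given0, params.pi1_given1 = 0.5, 0.5, 0.5
        resp = np.full((1, 4), np.nan)
        rts = np.array([[0.0, 2.0, 2.0, 2.0]])
        data = validate_dataset(resp, rts, 3)
        post = state_posteriors(data, _fake_fit(spec, params))
        assert post[0, 0, 1] > 0.95  # fastest category, hugely faster state 1

    def test_separates_true_states(self, small_hetero, small_hetero_fit):
        data, _truth, states, _lat = small_hetero
        post = state_posteriors(data, small_hetero_fit)
        mean_true_state_prob = np.mean(post[np.arange(data.n_persons)[:, None],
                                            np.arange(data.n_items)[None, :],
                                            states])
        assert mean_true_state_prob > 0.5

    def test_marginal_blend_matches_chain_occupancy(self, small_hetero, small_hetero_fit):
        data, *_ = small_hetero
        post = state_posteriors(data, small_hetero_fit)
        chain = chain_from_params(small_hetero_fit.estimates, small_hetero_fit.spec)
        marg = chain.initial.copy()
        occ = []
        for _ in range(data.n_items):
            occ.append(marg[1])
            marg = marg @ chain.transition
        assert post[:, :, 1].mean() == pytest.approx(np.mean(occ), abs=0.05)


class TestStandardizedRts:
    def test_location_scale_normalization_and_shift_invariance(self):
        rng = np.random.default_rng(8)
        t = np.exp(rng.normal(1, 0.5, (50, 4)))
        z = standardized_rts(t)
        assert np.allclose(np.nanmean(z, axis=0), 0.0, atol=1e-12)
        assert np.allclose(np.nanstd(z, axis=0, ddof=1), 1.0, atol=1e-12)
        t2 = t.copy()
        t2[:, 1] += 7.5
        assert np.allclose(standardized_rts(t2)[:, 1], z[:, 1], atol=1e-10)

    def test_ordering_preserved_and_missing_kept(self):
        t = np.array([[1.0, 5.0], [2.0, np.nan], [8.0, 1.0]])
        z = standardized_rts(t)
        assert np.isnan(z[1, 1])
        assert z[0, 0] < z[1, 0] < z[2, 0]

    def test_zero_sd_error(self):
        with pytest.raises(ValueError, match="zero"):
            standardized_rts(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))
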