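import numpy as np
import pytest

from hmmixrt import (LatentPoint, ModelSpec, item_information_response, pcm_pmf,
                     prob_correct, response_pmf, rt_category_information)
from hmmixrt.measurement import pcm_category_probs

from conftest import random_params


class TestProbCorrect:
    def test_logistic_symmetry(self):
        assert prob_correct(LatentPoint(0.0, 0.0), 1.0, 0.0) == pytest.approx(0.5)

    def test_three_parameter_value(self):
        # alpha=2, beta=1, gamma=.3 at theta=0: .3 + .7*logistic(1)
        got = prob_correct(LatentPoint(0.0, 0.0), 2.0, 1.0, 0.3)
        assert got == pytest.approx(0.81174, abs=1e-5)

    def test_lower_asymptote(self):
        assert prob_correct(LatentPoint(-40.0, 0.0), 1.0, 0.0, 0.3) == pytest.approx(0.3, abs=1e-9)

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            prob_correct(LatentPoint(0.0, 0.0), 1.0, 0.0, 1.0)


class TestResponsePmf:
    def setup_method(self):
        self.spec = ModelSpec("hetero_markov", 3, 3)
        self.params = random_params(self.spec, np.random.default_rng(1))

    def test_normalization(self):
        pt = LatentPoint(0.7, -0.2)
        total = (response_pmf(1, pt, 1, self.params, self.spec, item=2)
                 + response_pmf(0, pt, 1, self.params, self.spec, item=2))
        assert total == pytest.approx(1.0)

    def test_zero_discrimination_is_flat(self):
        self.params.alpha0[0] = 0.0
        self.params.beta0[0] = 0.0
        for theta in (-3.0, 0.0, 4.0):
            assert response_pmf(1, LatentPoint(theta, 0.0), 0, self.params, self.spec,
                                item=0) == pytest.approx(0.5)

    def test_design_value(self):
        # alpha0=1.5, beta0=-2 at theta=0: logistic(-2)
        self.params.alpha0[1] = 1.5
        self.params.beta0[1] = -2.0
        got = response_pmf(1, LatentPoint(0.0, 0.0), 0, self.params, self.spec, item=1)
        assert got == pytest.approx(0.11920, abs=1e-5)

    def test_state1_rejected_for_baseline(self):
        spec = ModelSpec("baseline", 3, 3)
        p = random_params(spec, np.random.default_rng(2))
        with pytest.raises(ValueError, match="single state"):
            response_pmf(1, LatentPoint(0.0, 0.0), 1, p, spec)


class TestPcmPmf:
    def test_all_exponents_zero(self):
        spec = ModelSpec("hetero_markov", 1, 2)
        p = random_params(spec, np.random.default_rng(3))
        p.nu = np.zeros((1, 1))
        p.lam = np.zeros(1)
        probs = [pcm_pmf(t, LatentPoint(0.0, 0.3), 0, p, spec) for t in (0, 1)]
        assert np.allclose(probs, [0.5, 0.5])

    def test_state1_location_shift(self):
        spec = ModelSpec("hetero_markov", 1, 2)
        p = random_params(spec, np.random.default_rng(4))
        p.nu = np.zeros((1, 1))
        p.lam = np.zeros(1)
        p.delta1, p.sigma1 = 0.5, 1.0
        probs = [pcm_pmf(t, LatentPoint(0.0, 0.0), 1, p, spec) for t in (0, 1)]
        assert np.allclose(probs, [0.62246, 0.37754], atol=1e-5)

    def test_adjacent_logit_identity(self):
        spec = ModelSpec("hetero_markov", 2, 5)
        rng = np.random.default_rng(5)
        p = random_params(spec, rng)
        tau = 0.8
        for state, delta, sigma in ((0, 0.0, 1.0), (1, p.delta1, p.sigma1)):
            probs = [pcm_pmf(t, LatentPoint(0.0, tau), state, p, spec, item=1)
                     for t in range(5)]
            for t in range(1, 5):
                expected = (p.nu[1, t - 1] - delta - p.lam[1] * tau) / sigma
                assert np.log(probs[t] / probs[t - 1]) == pytest.approx(expected, abs=1e-9)

    def test_normalization_many_draws(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            T = int(rng.integers(2, 7))
            probs = pcm_category_probs(rng.normal(), rng.normal(0, 1.5, T - 1),
                                       rng.uniform(0, 2), rng.normal(), rng.uniform(0.2, 3))
            assert abs(probs.sum() - 1.0) < 1e-12
            assert (probs > 0).all()

    def test_stochastically_decreasing_in_tau(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            T = int(rng.integers(2, 6))
            nu = rng.normal(0, 1.5, T - 1)
            lam = rng.uniform(0.1, 2.0)
            t1, t2 = sorted(rng.normal(0, 1.5, 2))
            p_lo = pcm_category_probs(t1, nu, lam, 0.0, 1.0)
            p_hi = pcm_category_probs(t2, nu, lam, 0.0, 1.0)
            # larger tau puts more mass on the fast (low) categories
            assert np.all(np.cumsum(p_hi)[:-1] >= np.cumsum(p_lo)[:-1] - 1e-12)

    def test_homoscedastic_limit_matches_state0(self):
        spec = ModelSpec("hetero_markov", 1, 4)
        p = random_params(spec, np.random.default_rng(8))
        p.delta1, p.sigma1 = 1e-12, 1.0
        for t in range(4):
            pt = LatentPoint(0.0, -0.4)
            assert pcm_pmf(t, pt, 1, p, spec) == pytest.approx(pcm_pmf(t, pt, 0, p, spec))


class TestInformation:
    def test_two_parameter_information_value(self):
        assert item_information_response(0.0, 1.0, 0.0) == pytest.approx(0.25)

    def test_alpha_squared_scaling(self):
        grid = np.linspace(-4, 4, 101)
        i1 = item_information_response(grid, 1.0, 0.0).max()
        i2 = item_information_response(grid, 2.0, 0.0).max()
        assert i2 / i1 == pytest.approx(4.0, rel=1e-6)

    def test_three_parameter_information_matches_numeric(self):
        grid = np.linspace(-3, 3, 25)
        h = 1e-5
        p = lambda th: 0.3 + 0.7 / (1 + np.exp(-(2.0 * th + 1.0)))  # noqa: E731
        num = ((p(grid + h) - p(grid - h)) / (2 * h)) ** 2 / (p(grid) * (1 - p(grid)))
        assert np.allclose(item_information_response(grid, 2.0, 1.0, 0.3), num, rtol=1e-6)

    def test_rt_information_zero_without_loading(self):
        grid = np.linspace(-3, 3, 11)
        info = rt_category_information(grid, np.array([1.0, -1.0]), 0.0)
        assert np.allclose(info, 0.0)

    def test_rt_information_matches_finite_difference(self):
        rng = np.random.default_rng(9)
        grid = np.linspace(-2, 2, 9)
        for _ in range(5):
            nu = rng.normal(0, 1.5, 4)
            lam = rng.uniform(0.2, 1.5)
            h = 1e-4
            num = []
            for tau in grid:
                def logp(t_, x):
                    return np.log(pcm_category_probs(x, nu, lam, 0.0, 1.0)[t_])
                p0 = pcm_category_probs(tau, nu, lam, 0.0, 1.0)
                d2 = [(logp(t_, tau + h) - 2 * logp(t_, tau) + logp(t_, tau - h)) / h**2
                      for t_ in range(5)]
                num.append(-np.dot(p0, d2))
            got = rt_category_information(grid, nu, lam)
            assert np.allclose(got, num, atol=1e-5)

    def test_equidistant_thresholds_concentrate_information(self):
        # thresholds reproducing the normal-quantile bin probabilities at tau=0
        # vs the uniform bins of equidistant percentiles
        pn = np.array([0.0228, 0.2297, 0.4950, 0.2298, 0.0227])
        nu_normal = np.log(pn[1:] / pn[:-1])
        nu_equi = np.zeros(4)
        peak_equi = rt_category_information(0.0, nu_equi, 1.0)
        peak_normal = rt_category_information(0.0, nu_normal, 1.0)
        assert peak_equi / peak_normal > 1.0
        # and the normal-quantile scheme holds information better away from 0
        far_equi = rt_category_information(2.5, nu_equi, 1.0)
        far_normal = rt_category_information(2.5, nu_normal, 1.0)
        assert far_normal > far_equi
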