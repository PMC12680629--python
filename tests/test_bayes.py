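import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.optimize import minimize

from iepfit import (
    GammaPriorPair,
    IEPParams,
    MCChain,
    fit_mle,
    lindley_estimates,
    log_posterior_kernel,
    log_prior,
    mh_sample,
    posterior_mean_quadrature,
    sample,
    sel_estimate,
    tk_estimates,
)
from iepfit.bayes import _tk_expectation, lindley_adjustment, prior_gradient, random_walk_metropolis


class TestPrior:
    def test_density_integrates_to_one(self):
        pr = GammaPriorPair(1.5, 2.0, 2.0, 0.7)
        total, _ = dblquad(
            lambda l, a: np.exp(log_prior(IEPParams(a, l), pr)),
            1e-9, 60.0, 1e-9, 60.0, epsabs=1e-9,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_shape_one_reduces_to_exponential(self):
        pr = GammaPriorPair(1.0, 2.0, 1.0, 3.0)
        p1, p2 = IEPParams(0.5, 0.5), IEPParams(1.5, 2.5)
        diff = log_prior(p1, pr) - log_prior(p2, pr)
        expected = -2.0 * (p1.alpha - p2.alpha) - 3.0 * (p1.lam - p2.lam)
        assert diff == pytest.approx(expected, abs=1e-12)

    def test_gradient_matches_finite_differences(self, default_priors):
        p = IEPParams(1.3, 0.8)
        g = prior_gradient(p, default_priors)
        h = 1e-7
        fd_a = (log_prior(IEPParams(p.alpha + h, p.lam), default_priors)
                - log_prior(IEPParams(p.alpha - h, p.lam), default_priors)) / (2 * h)
        fd_l = (log_prior(IEPParams(p.alpha, p.lam + h), default_priors)
                - log_prior(IEPParams(p.alpha, p.lam - h), default_priors)) / (2 * h)
        np.testing.assert_allclose(g, [fd_a, fd_l], rtol=1e-6)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GammaPriorPair(gamma1=0.0)


class TestPosteriorKernel:
    def test_kernel_differences_equal_loglik_plus_prior(self, afr, default_priors):
        from iepfit import log_likelihood

        p1, p2 = IEPParams(1.0, 0.7), IEPParams(0.9, 0.6)
        dk = log_posterior_kernel(afr, p1, default_priors) - log_posterior_kernel(afr, p2, default_priors)
        direct = (log_likelihood(afr, p1) + log_prior(p1, default_priors)) - (
            log_likelihood(afr, p2) + log_prior(p2, default_priors)
        )
        assert dk == pytest.approx(direct, abs=1e-12)

    def test_near_flat_prior_mode_is_mle(self, afr, afr_fit):
        flat = GammaPriorPair(1.0, 1e-8, 1.0, 1e-8)
        res = minimize(
            lambda th: -log_posterior_kernel(afr, IEPParams(*np.exp(th)), flat),
            np.log(afr_fit.params.as_array()),
            method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14},
        )
        mode = np.exp(res.x)
        assert mode[0] == pytest.approx(afr_fit.params.alpha, abs=1e-4)
        assert mode[1] == pytest.approx(afr_fit.params.lam, abs=1e-4)

    def test_finite_at_mle_on_all_regions(self, default_priors):
        from iepfit import REGION_CODES, load_region

        for code in REGION_CODES:
            s = load_region(code).sample
            fit = fit_mle(s)
            assert np.isfinite(log_posterior_kernel(s, fit.params, default_priors))


class TestLindley:
    def test_zero_correction_returns_mle_exactly(self, afr_fit):
        sigma = afr_fit.info.covariance()
        corr = lindley_adjustment(sigma, np.zeros(2), lambda i, j, k: 0.0, np.array([1.0, 0.0]))
        assert corr == 0.0

    def test_close_to_quadrature_oracle(self, default_priors):
        s = sample(100, IEPParams(2, 2), seed=21)
        fit = fit_mle(s)
        est = lindley_estimates(s, fit, default_priors)
        oracle = posterior_mean_quadrature(s, default_priors)
        assert abs(est.alpha - oracle.alpha) < 0.02
        assert abs(est.lam - oracle.lam) < 0.02

    def test_requires_converged_fit(self, afr, afr_fit, default_priors):
        from dataclasses import replace

        broken = replace(afr_fit, converged=False)
        with pytest.raises(Exception):
            lindley_estimates(afr, broken, default_priors)


class TestTierneyKadane:
    def test_constant_function_returns_constant(self, afr, afr_fit, default_priors):
        c = 3.7
        zero2 = lambda p: np.zeros(2)
        zero22 = lambda p: np.zeros((2, 2))
        val = _tk_expectation(
            afr, default_priors,
            logu_value=lambda p: np.log(c), logu_grad=zero2, logu_hess=zero22,
            start=afr_fit.params,
        )
        assert val == pytest.approx(c, rel=1e-10)

    def test_close_to_quadrature_oracle(self, default_priors):
        s = sample(100, IEPParams(2, 2), seed=22)
        est = tk_estimates(s, default_priors)
        oracle = posterior_mean_quadrature(s, default_priors)
        assert abs(est.alpha - oracle.alpha) < 0.01
        assert abs(est.lam - oracle.lam) < 0.01

    def test_afr_reference_estimates(self, afr, afr_fit, default_priors):
        est = tk_estimates(afr, default_priors, fit=afr_fit)
        assert est.alpha == pytest.approx(0.9645, abs=5e-4)
        assert est.lam == pytest.approx(0.6695, abs=5e-4)


def test_tk_beats_lindley_on_average(default_priors):
    """Laplace-based TK carries O(1/n^2) error vs Lindley's O(1/n)."""
    truth = IEPParams(2, 2)
    gaps = {"tk": [], "lindley": []}
    for n in (30, 100):
        for rep in range(25):
            s = sample(n, truth, seed=1000 * n + rep)
            try:
                fit = fit_mle(s)
                oracle = posterior_mean_quadrature(s, default_priors, n_nodes=96)
                tk = tk_estimates(s, default_priors, fit=fit)
                li = lindley_estimates(s, fit, default_priors)
            except Exception:
                continue
            gaps["tk"].append(abs(tk.alpha - oracle.alpha) + abs(tk.lam - oracle.lam))
            gaps["lindley"].append(abs(li.alpha - oracle.alpha) + abs(li.lam - oracle.lam))
    assert np.mean(gaps["tk"]) <= np.mean(gaps["lindley"])


def test_shrinkage_direction_at_small_n(default_priors):
    """Prior means (0.5 for alpha, 2 for lam) pull the Bayes estimates."""
    truth = IEPParams(0.8, 0.5)
    mle_a, tk_a, mle_l, tk_l = [], [], [], []
    for rep in range(120):
        s = sample(10, truth, seed=rep)
        try:
            fit = fit_mle(s)
            tk = tk_estimates(s, default_priors, fit=fit)
        except Exception:
            continue
        mle_a.append(fit.params.alpha)
        tk_a.append(tk.alpha)
        mle_l.append(fit.params.lam)
        tk_l.append(tk.lam)
    assert np.mean(tk_a) < np.mean(mle_a)   # alpha pulled down toward 0.5
    assert np.mean(tk_l) > np.mean(mle_l)   # lam pulled up toward 2


class TestMetropolis:
    def test_known_target_recovery(self):
        rng = np.random.default_rng(99)
        log_target = lambda th: -0.5 * float(th @ th)
        states, rate = random_walk_metropolis(
            log_target, np.zeros(2), (2.4**2 / 2) * np.eye(2), 50_000, rng
        )
        retained = states[5000:]
        assert np.max(np.abs(retained.mean(axis=0))) < 0.05
        assert np.max(np.abs(np.cov(retained.T) - np.eye(2))) < 0.1
        assert 0.2 < rate < 0.6

    def test_chain_bit_reproducible(self, afr, default_priors):
        c1 = mh_sample(afr, default_priors, n_iter=500, burn_in=100, seed=7)
        c2 = mh_sample(afr, default_priors, n_iter=500, burn_in=100, seed=7)
        assert np.array_equal(c1.draws, c2.draws)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_zero_scale_gives_constant_chain(self, afr, default_priors):
        chain = mh_sample(afr, default_priors, n_iter=200, burn_in=0, scale=0.0, seed=1)
        assert np.all(chain.draws == chain.draws[0])

    def test_posterior_mean_matches_oracle(self, default_priors):
        s = sample(50, IEPParams(2, 2), seed=31)
        chain = mh_sample(s, default_priors, n_iter=20_000, burn_in=4_000, seed=5)
        est = sel_estimate(chain)
        oracle = posterior_mean_quadrature(s, default_priors)
        retained = chain.retained
        # batch-means Monte Carlo standard errors (autocorrelation-aware)
        nb = 20
        batches = retained[: (len(retained) // nb) * nb].reshape(nb, -1, 2).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / np.sqrt(nb)
        assert abs(est.alpha - oracle.alpha) < 3 * se[0]
        assert abs(est.lam - oracle.lam) < 3 * se[1]

    def test_draws_positive_and_acceptance_recorded(self, afr, default_priors):
        chain = mh_sample(afr, default_priors, n_iter=1000, burn_in=200, seed=3)
        assert np.all(chain.retained > 0)
        assert 0 < chain.acceptance_rate <= 1

    def test_bad_iteration_counts_rejected(self, afr, default_priors):
        with pytest.raises(ValueError):
            mh_sample(afr, default_priors, n_iter=100, burn_in=100)


class TestSelEstimate:
    def test_constant_chain(self):
        draws = np.tile([2.0, 3.0], (50, 1))
        chain = MCChain(draws=draws, n_iter=50, burn_in=10, acceptance_rate=1.0)
        est = sel_estimate(chain)
        assert (est.alpha, est.lam) == (2.0, 3.0)

    def test_two_draw_mean(self):
        chain = MCChain(draws=np.array([[1.0, 1.0], [3.0, 3.0]]), n_iter=2, burn_in=0, acceptance_rate=1.0)
        est = sel_estimate(chain)
        assert (est.alpha, est.lam) == (2.0, 2.0)

    def test_empty_retained_rejected(self):
        chain = MCChain(draws=np.empty((0, 2)), n_iter=0, burn_in=0, acceptance_rate=0.0)
        with pytest.raises(ValueError):
            sel_estimate(chain)


class TestQuadratureOracle:
    def test_bernstein_von_mises_limit(self):
        # flat-ish prior, large n: posterior mean converges to the MLE
        flat = GammaPriorPair(1.0, 1e-6, 1.0, 1e-6)
        s = sample(2000, IEPParams(2, 2), seed=41)
        fit = fit_mle(s)
        oracle = posterior_mean_quadrature(s, flat)
        assert abs(oracle.alpha - fit.params.alpha) < 0.01
        assert abs(oracle.lam - fit.params.lam) < 0.01

    def test_node_count_insensitivity(self, default_priors):
        s = sample(40, IEPParams(1.5, 1.0), seed=55)
        coarse = posterior_mean_quadrature(s, default_priors, n_nodes=96)
        fine = posterior_mean_quadrature(s, default_priors, n_nodes=200)
        assert coarse.alpha == pytest.approx(fine.alpha, rel=1e-6)
        assert coarse.lam == pytest.approx(fine.lam, rel=1e-6)


def test_all_estimators_converge_to_mle_with_vanishing_prior():
    flat = GammaPriorPair(1.0, 1e-6, 1.0, 1e-6)
    s = sample(800, IEPParams(1.5, 0.8), seed=61)
    fit = fit_mle(s)
    li = lindley_estimates(s, fit, flat)
    tk = tk_estimates(s, flat, fit=fit)
    chain = mh_sample(s, flat, n_iter=8000, burn_in=2000, seed=8)
    mc = sel_estimate(chain)
    for est in (li, tk, mc):
        assert abs(est.alpha - fit.params.alpha) < 0.05
        assert abs(est.lam - fit.params.lam) < 0.05
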