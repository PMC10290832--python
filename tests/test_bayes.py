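"""Gibbs/RWM sampler, pooled posterior draws, equitailed and HPD intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import weibullmeans as wm
from weibullmeans.bayes import (
    GammaPrior,
    log_unnormalized_posterior_k,
    rwm_update_k,
    sample_cprime,
)


def _sample(values, gid="g"):
    return wm.ObservedSample(gid, np.asarray(values, dtype=float))


class TestShapeConditional:
    def test_off_support_is_minus_inf(self, wind_samples):
        lp = log_unnormalized_posterior_k(-0.5, 1.0, wind_samples[0], GammaPrior())
        assert lp == -np.inf

    def test_prior_limit_shape(self):
        """With a tiny pseudo-sample weight the conditional tracks the prior.

        Compare the log-density difference of two k values against the
        gamma(v1, z1) prior using a two-point sample carrying negligible
        likelihood contribution removed explicitly.
        """
        prior = GammaPrior(v1=3.0, z1=2.0, v2=1.0, z2=1.0)
        sample = _sample([1.0, 1.0 + 1e-12])
        # x ~= 1: sum(log x) ~= 0 and sum(x**k) ~= n, so the conditional is
        # (n + v1 - 1) log k - z1 k - c' n; subtracting the likelihood part
        # must leave the gamma(v1, z1) log-kernel (v1 - 1) log k - z1 k.
        for k1, k2 in [(0.5, 1.5), (2.0, 4.0)]:
            d = log_unnormalized_posterior_k(k1, 1.0, sample, prior) - \
                log_unnormalized_posterior_k(k2, 1.0, sample, prior)
            d_lik = sample.n * np.log(k1 / k2)
            d_prior = (prior.v1 - 1) * np.log(k1 / k2) - prior.z1 * (k1 - k2)
            assert d == pytest.approx(d_lik + d_prior, abs=1e-9)

    def test_density_normalizes_by_quadrature(self):
        """exp of the log-conditional integrates to a finite positive mass."""
        sample = _sample([0.8, 1.1, 1.5])
        prior = GammaPrior()
        cprime = 1.0
        grid = np.linspace(1e-3, 40, 4000)
        vals = np.exp([
            log_unnormalized_posterior_k(k, cprime, sample, prior) for k in grid
        ])
        mass = integrate.trapezoid(vals, grid)
        assert np.isfinite(mass) and mass > 0
        # normalized density integrates to 1 on the grid
        assert integrate.trapezoid(vals / mass, grid) == pytest.approx(1.0, abs=1e-6)


class TestConjugateScaleDraw:
    def test_distribution_matches_closed_form_gamma(self, wind_samples, rng):
        """KS test of c' draws under fixed k against Gamma(n+v2, z2+sum(x**k))."""
        sample = wind_samples[0]
        prior = GammaPrior()
        k = 4.0
        draws = np.array([sample_cprime(k, sample, prior, rng) for _ in range(50_000)])
        shape = sample.n + prior.v2
        rate = prior.z2 + np.sum(sample.values ** k)
        p = stats.kstest(draws, stats.gamma(a=shape, scale=1.0 / rate).cdf).pvalue
        assert p > 0.01

    def test_moment_identity(self, wind_samples, rng):
        sample = wind_samples[1]
        prior = GammaPrior()
        k = 3.0
        draws = np.array([sample_cprime(k, sample, prior, rng) for _ in range(10_000)])
        shape = sample.n + prior.v2
        rate = prior.z2 + np.sum(sample.values ** k)
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se


class _StubRng:
    """Deterministic stand-in driving the RWM proposal and accept draws."""

    def __init__(self, eps, u=0.5):
        self._eps, self._u = eps, u

    def standard_normal(self):
        return self._eps

    def random(self):
        return self._u


class TestRwmUpdate:
    def test_null_proposal_always_accepted(self, wind_samples):
        k_new, accepted = rwm_update_k(
            2.0, 1.0, wind_samples[0], GammaPrior(), sigma=1.0,
            rng=_StubRng(eps=0.0, u=1.0 - 1e-12),
        )
        assert accepted and k_new == 2.0

    def test_nonpositive_proposal_rejected(self, wind_samples):
        k_new, accepted = rwm_update_k(
            0.5, 1.0, wind_samples[0], GammaPrior(), sigma=1.0,
            rng=_StubRng(eps=-1.0, u=0.0),
        )
        assert not accepted and k_new == 0.5

    def test_long_run_matches_quadrature_density(self):
        """Marginal k draws on a 3-point sample vs the normalized conditional.

        The scale parameter is held fixed so the RWM chain targets exactly
        the one-dimensional shape conditional, whose CDF is computed by
        quadrature; the empirical CDF must agree to KS distance 0.02.
        """
        sample = _sample([0.8, 1.1, 1.5])
        prior = GammaPrior()
        cprime = 1.2
        rng = np.random.default_rng(99)
        T, burn = 60_000, 2_000
        k = 1.5
        draws = np.empty(T)
        for t in range(T):
            k, _ = rwm_update_k(k, cprime, sample, prior, sigma=1.5, rng=rng)
            draws[t] = k
        draws = draws[burn:]
        grid = np.linspace(1e-3, 60, 6000)
        logpdf = np.array([
            log_unnormalized_posterior_k(v, cprime, sample, prior) for v in grid
        ])
        pdf = np.exp(logpdf - logpdf.max())
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestGibbsChain:
    def test_seed_determinism(self, wind_samples):
        config = wm.McmcConfig(T=800, burn_in=200, seed=5)
        a = wm.gibbs_chain(wind_samples[0], config=config)
        b = wm.gibbs_chain(wind_samples[0], config=config)
        assert np.array_equal(a.mu, b.mu)
        assert a.accept_rate == b.accept_rate

    def test_posterior_mean_near_mle_at_n50(self, wind_samples, wind_fits):
        """Diffuse priors leave the n=50 posterior centred on the MLE mean."""
        chain = wm.gibbs_chain(
            wind_samples[0], config=wm.McmcConfig(T=20_000, burn_in=1000, seed=8)
        )
        mle_mu = wm.weibull_mean(wind_fits[0].c_hat, wind_fits[0].k_hat)
        assert chain.mu.mean() == pytest.approx(mle_mu, abs=0.02)

    def test_acceptance_rate_in_adapted_band(self, wind_samples):
        for sample in wind_samples:
            chain = wm.gibbs_chain(
                sample, config=wm.McmcConfig(T=5000, burn_in=1000, seed=3)
            )
            assert 0.15 < chain.accept_rate < 0.6

    def test_posterior_concentration(self):
        """95% HPD from n=500 data contains the true mean in >=90/100 chains."""
        c_true, k_true = 1.5, 2.5
        mu_true = wm.weibull_mean(c_true, k_true)
        gen = np.random.default_rng(42)
        hits = 0
        for i in range(100):
            x = c_true * gen.weibull(k_true, 500)
            chain = wm.gibbs_chain(
                _sample(x), config=wm.McmcConfig(T=1500, burn_in=500, seed=1000 + i)
            )
            interval = wm.hpd_interval(chain.mu, 0.95)
            hits += interval.contains(mu_true)
        assert hits >= 90


class TestPooling:
    def test_single_chain_identity(self, wind_samples):
        chain = wm.gibbs_chain(
            wind_samples[0], config=wm.McmcConfig(T=600, burn_in=100, seed=1)
        )
        pooled = wm.posterior_common_mean([chain])
        assert np.allclose(pooled, chain.mu)

    def test_pooled_draw_convexity(self, wind_samples):
        chains = [
            wm.gibbs_chain(s, config=wm.McmcConfig(T=600, burn_in=100, seed=i))
            for i, s in enumerate(wind_samples)
        ]
        pooled = wm.posterior_common_mean(chains)
        mus = np.stack([c.mu for c in chains])
        assert np.all(pooled >= mus.min(axis=0) - 1e-12)
        assert np.all(pooled <= mus.max(axis=0) + 1e-12)

    def test_equal_variance_stub_averages(self):
        k = np.full(10, 2.0)
        c = np.full(10, 1.0)
        a = wm.PosteriorChain(k=k, cprime=c, c=c, mu=np.full(10, 1.0),
                              accept_rate=1.0, n=30)
        b = wm.PosteriorChain(k=k, cprime=c, c=c, mu=np.full(10, 3.0),
                              accept_rate=1.0, n=30)
        assert np.allclose(wm.posterior_common_mean([a, b]), 2.0)

    def test_length_mismatch_rejected(self, wind_samples):
        a = wm.gibbs_chain(wind_samples[0], config=wm.McmcConfig(T=300, burn_in=100, seed=0))
        b = wm.gibbs_chain(wind_samples[1], config=wm.McmcConfig(T=400, burn_in=100, seed=0))
        with pytest.raises(ValueError):
            wm.posterior_common_mean([a, b])


class TestIntervals:
    def test_equitailed_known_quantiles(self, rng):
        draws = rng.standard_normal(200_000)
        interval = wm.equitailed_interval(draws, 0.95)
        assert interval.lower == pytest.approx(-1.96, abs=0.03)
        assert interval.upper == pytest.approx(1.96, abs=0.03)

    def test_constant_draws_collapse(self):
        interval = wm.equitailed_interval(np.full(100, 1.7), 0.95)
        assert interval.lower == interval.upper == pytest.approx(1.7)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(10, 2000),
        level=st.floats(0.5, 0.99),
    )
    def test_hpd_is_shortest_count_matched_window(self, seed, n, level):
        """Exact guarantee: no window holding the same number of sorted draws
        is shorter, and the HPD window does hold that many draws."""
        draws = np.random.default_rng(seed).gamma(2.0, size=n)
        hpd = wm.hpd_interval(draws, level)
        d = np.sort(draws)
        w = min(max(int(np.ceil(level * n)), 2), n)
        central = d[(n - w) // 2 + w - 1] - d[(n - w) // 2]
        assert hpd.length <= central + 1e-12
        inside = np.count_nonzero((draws >= hpd.lower) & (draws <= hpd.upper))
        assert inside >= w

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_hpd_never_longer_than_equitailed_mcmc_scale(self, seed):
        """At MCMC-sized draw counts the HPD also beats the interpolated
        equitailed interval."""
        draws = np.random.default_rng(seed).gamma(2.0, size=19_000)
        hpd = wm.hpd_interval(draws, 0.95)
        et = wm.equitailed_interval(draws, 0.95)
        assert hpd.length <= et.length + 1e-12

    def test_hpd_matches_bruteforce_and_shifts_left_on_skew(self, rng):
        draws = rng.exponential(1.0, 5001)
        hpd = wm.hpd_interval(draws, 0.95)
        et = wm.equitailed_interval(draws, 0.95)
        assert hpd.lower < et.lower
        # brute force over all windows of the required size
        d = np.sort(draws)
        w = int(np.ceil(0.95 * d.size))
        widths = [d[j + w - 1] - d[j] for j in range(d.size - w + 1)]
        j = int(np.argmin(widths))
        assert hpd.lower == pytest.approx(d[j])
        assert hpd.upper == pytest.approx(d[j + w - 1])

    def test_hpd_close_to_equitailed_for_symmetric_draws(self, rng):
        draws = rng.standard_normal(100_000)
        hpd = wm.hpd_interval(draws, 0.95)
        et = wm.equitailed_interval(draws, 0.95)
        assert hpd.lower == pytest.approx(et.lower, abs=0.05)
        assert hpd.upper == pytest.approx(et.upper, abs=0.05)

    def test_hpd_agrees_with_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        draws = rng.gamma(3.0, size=20_000)
        ours = wm.hpd_interval(draws, 0.95)
        lo, hi = arviz.hdi(draws, hdi_prob=0.95)
        assert ours.lower == pytest.approx(lo, abs=0.02)
        assert ours.upper == pytest.approx(hi, abs=0.02)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            wm.hpd_interval(np.array([1.0]), 0.95)


def test_full_pipeline_seed_determinism(wind_samples):
    config = wm.McmcConfig(T=1500, burn_in=300, seed=21)
    et1, hpd1, _, _ = wm.bayes_intervals(wind_samples, config=config)
    et2, hpd2, _, _ = wm.bayes_intervals(wind_samples, config=config)
    assert (et1.lower, et1.upper) == (et2.lower, et2.upper)
    assert (hpd1.lower, hpd1.upper) == (hpd2.lower, hpd2.upper)
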