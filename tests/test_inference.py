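"""Likelihood, priors, MCMC machinery, convergence diagnostics and summaries."""

import math

import numpy as np
import pytest
import scipy.stats as st

from burstkit.inference import (
    ChainSet,
    InsufficientDataError,
    PriorSpec,
    TelegraphModel,
    log_likelihood,
    log_prior,
    mle_fit,
    rhat,
    run_mcmc,
    summarize,
)
from burstkit.model import (
    ModelSpec,
    RateParameters,
    SteadyStateDistribution,
    steady_state,
)
from burstkit.simulate import SimulationConfig, gillespie_counts

K_DECAY = math.log(2.0) / 300.0  # 5-hour half-life, per minute


@pytest.fixture(scope="module")
def simulated_gene():
    """Counts from known two-state rates, with the truth attached."""
    true = RateParameters.two_state(0.008, 0.08, 0.06, K_DECAY)
    spec = ModelSpec(2, n_alleles=2)
    counts = sum(
        gillespie_counts(SimulationConfig(spec=spec, rates=true, n_cells=3000, seed=s))
        for s in (42, 43)
    )
    return true, counts


@pytest.fixture(scope="module")
def fitted(simulated_gene):
    true, counts = simulated_gene
    model = TelegraphModel(counts, k_decay=K_DECAY, n_alleles=2)
    return true, counts, model.fit(n_chains=4, n_samples=20_000, seed=7)


class TestLogLikelihood:
    def test_uniform_distribution(self):
        dist = SteadyStateDistribution(np.full(10, 0.1))
        counts = np.arange(10).repeat(10)
        assert log_likelihood(dist, counts) == pytest.approx(100 * np.log(0.1), abs=1e-9)

    def test_poisson_closed_form(self):
        dist = steady_state(ModelSpec(1, 1), RateParameters.one_state(2.0, 1.0))
        # ln e^-2 + ln 2e^-2 + ln 2e^-2 = -6 + ln 4
        assert log_likelihood(dist, [0, 1, 2]) == pytest.approx(-6 + np.log(4), abs=1e-8)

    def test_matches_per_cell_loop(self, rng):
        probs = rng.dirichlet(np.ones(15))
        dist = SteadyStateDistribution(probs)
        counts = rng.integers(0, 15, size=200)
        brute = sum(math.log(probs[c]) for c in counts)
        assert log_likelihood(dist, counts) == pytest.approx(brute, rel=1e-12)

    def test_out_of_support_count_is_floored(self):
        dist = SteadyStateDistribution(np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="floored"):
            ll = log_likelihood(dist, [0, 7])
        assert ll <= math.log(0.5) + math.log(1e-300) + 1.0


class TestPrior:
    def test_log_space_moment_inversion(self):
        prior = PriorSpec.default(2)
        sigma2 = math.log(1 + 10.0**2)
        assert sigma2 == pytest.approx(4.61512, abs=1e-5)
        assert prior.sigma_log[0] ** 2 == pytest.approx(sigma2, rel=1e-12)
        assert prior.mu_log[0] == pytest.approx(math.log(0.01) - sigma2 / 2, rel=1e-12)
        assert prior.mu_log[0] == pytest.approx(-6.91273, abs=1e-4)

    def test_density_at_log_median(self):
        prior = PriorSpec((0.01,), cv=10.0)
        x = math.exp(prior.mu_log[0])
        sigma = prior.sigma_log[0]
        expected = math.log(1.0 / (x * sigma * math.sqrt(2 * math.pi)))
        assert log_prior(prior, [x]) == pytest.approx(expected, rel=1e-10)

    def test_symmetry_in_log_space(self):
        prior = PriorSpec((0.05,), cv=10.0)
        mu = prior.mu_log[0]
        up = log_prior(prior, [math.exp(mu + 1)]) + (mu + 1)
        down = log_prior(prior, [math.exp(mu - 1)]) + (mu - 1)
        # after removing the Jacobian the log-density deficit is symmetric
        assert up == pytest.approx(down, rel=1e-10)

    def test_nonpositive_rate(self):
        prior = PriorSpec.default(2)
        assert log_prior(prior, [0.01, 0.1, 0.0]) == -math.inf

    def test_rate_parameters_accepted(self):
        prior = PriorSpec.default(2)
        r = RateParameters.two_state(0.01, 0.1, 0.05, K_DECAY)
        assert log_prior(prior, r) == pytest.approx(log_prior(prior, [0.01, 0.1, 0.05]))


class TestRunMcmc:
    def test_same_seed_identical_chains(self):
        counts = st.poisson.rvs(3.0, size=300, random_state=1)
        spec = ModelSpec(2, n_alleles=1)
        kw = dict(n_chains=2, n_samples=2000, seed=11)
        c1 = run_mcmc(counts, spec, None, K_DECAY, **kw)
        c2 = run_mcmc(counts, spec, None, K_DECAY, **kw)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.logliks, c2.logliks)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            run_mcmc(np.zeros(10, dtype=int), ModelSpec(2, 1), None, K_DECAY)
        with pytest.raises(InsufficientDataError):
            run_mcmc(np.array([], dtype=int), ModelSpec(2, 1), None, K_DECAY)

    def test_recovery_and_convergence(self, fitted):
        """Posterior credible intervals cover the generating rates and the
        four chains converge on well-identified synthetic data."""
        true, _counts, res = fitted
        post = res.posterior
        assert post.rhat_max < 1.05
        ci = res.conf_int()
        assert ci.loc["k_on", "2.5%"] <= true.k_on <= ci.loc["k_on", "97.5%"]
        assert ci.loc["burst_size", "2.5%"] <= true.burst_size <= ci.loc["burst_size", "97.5%"]


class TestRhat:
    def test_duplicated_chain_is_one(self, rng):
        # B = 0 exactly, so psrf = sqrt((n-1)/n) -> 1 up to the finite-n term
        x = rng.normal(size=1000)
        chains = np.stack([x, x])
        assert rhat(chains, split=False) == pytest.approx(math.sqrt(999 / 1000), abs=1e-12)
        assert rhat(chains, split=False) == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_formula(self, rng):
        # two chains N(0,1) and N(10,1): unsplit psrf ~= sqrt(999/1000 + 50)
        n = 1000
        chains = np.stack([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        W = np.mean(np.var(chains, axis=1, ddof=1))
        B_over_n = np.var(chains.mean(axis=1), ddof=1)
        oracle = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert oracle == pytest.approx(7.14, abs=0.3)
        assert rhat(chains, split=False) == pytest.approx(oracle, rel=1e-12)

    def test_same_distribution_chains_near_one(self, rng):
        chains = rng.normal(size=(2, 1000))
        assert 0.99 <= rhat(chains, split=False) <= 1.02

    def test_agrees_with_arviz_on_converged_chains(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(size=(4, 2000))
        ours = rhat(chains, split=True)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_zero_variance_defined_as_one(self):
        chains = np.ones((2, 100))
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            assert rhat(chains, split=False) == 1.0


def _chainset_from_draws(draws: np.ndarray, names, k_decay=K_DECAY) -> ChainSet:
    """Wrap raw log-rate draws (chains x n x p) for summary tests."""
    spec = ModelSpec(2, n_alleles=1)
    return ChainSet(
        samples=draws,
        logliks=np.zeros(draws.shape[:2]),
        param_names=list(names),
        n_samples=draws.shape[1],
        n_warmup=0,
        acceptance=np.full(draws.shape[0], 0.3),
        seed=0,
        spec=spec,
        k_decay=k_decay,
        prior=PriorSpec.default(2),
    )


class TestSummarize:
    def test_perfectly_correlated_burst_size(self, rng):
        k_off = np.exp(rng.normal(-2, 0.5, size=(2, 500)))
        k_on = np.full((2, 500), 0.01)
        draws = np.stack([np.log(k_on), np.log(k_off), np.log(2 * k_off)], axis=-1)
        cs = _chainset_from_draws(draws, ["k_on", "k_off", "k_eject"])
        summary = summarize(cs, np.array([0, 1, 2]))
        burst = summary.params["burst_size"]
        assert burst.median == pytest.approx(2.0, rel=1e-12)
        assert burst.mad == pytest.approx(0.0, abs=1e-12)

    def test_mad_definition_unscaled(self):
        draws = np.log(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        full = np.stack([draws, draws])[:, :, None]
        full = np.repeat(full, 3, axis=2)
        cs = _chainset_from_draws(full, ["k_on", "k_off", "k_eject"])
        summary = summarize(cs, np.array([0, 1]))
        assert summary.params["k_on"].median == pytest.approx(3.0)
        assert summary.params["k_on"].mad == pytest.approx(1.0)

    def test_shuffling_changes_burst_size_spread(self, rng):
        # correlated k_off / k_eject draws: the joint ratio is tight, the
        # independently shuffled ratio is not
        z = rng.normal(0, 1.0, size=(2, 2000))
        k_off = np.exp(-2 + z)
        k_eject = np.exp(-1.3 + z + rng.normal(0, 0.05, size=z.shape))
        draws = np.stack([np.full_like(z, -4.6), np.log(k_off), np.log(k_eject)], axis=-1)
        cs = _chainset_from_draws(draws, ["k_on", "k_off", "k_eject"])
        joint_mad = summarize(cs, np.array([0, 1])).params["burst_size"].mad
        shuffled = draws.copy()
        perm = rng.permutation(2000)
        shuffled[:, :, 2] = shuffled[:, perm, 2]
        cs_sh = _chainset_from_draws(shuffled, ["k_on", "k_off", "k_eject"])
        shuffled_mad = summarize(cs_sh, np.array([0, 1])).params["burst_size"].mad
        assert joint_mad < 0.25 * shuffled_mad


class TestMle:
    def test_one_state_mle_is_sample_mean(self):
        counts = st.poisson.rvs(4.2, size=2000, random_state=3)
        params, _ll = mle_fit(counts, ModelSpec(1, n_alleles=1), K_DECAY, seed=0)
        assert params.k_eject / K_DECAY == pytest.approx(counts.mean(), rel=1e-4)

    def test_mle_within_posterior_interval(self, fitted):
        _true, counts, res = fitted
        params, ll = mle_fit(counts, ModelSpec(2, n_alleles=2), K_DECAY, seed=0)
        ci = res.conf_int()
        assert ci.loc["k_on", "2.5%"] <= params.k_on <= ci.loc["k_on", "97.5%"]
        # the maximum cannot be beaten by the posterior-median point
        assert ll >= res.llf - 1e-6


class TestResultsObject:
    def test_summary_text_and_accessors(self, fitted):
        _true, _counts, res = fitted
        text = res.summary()
        assert "burst_size" in text and "r-hat" in text
        assert set(res.params.index) >= {"k_on", "k_off", "k_eject", "off_time", "burst_size"}
        assert (res.mad >= 0).all()
        ci = res.conf_int()
        assert (ci["2.5%"] <= ci["97.5%"]).all()

    def test_predicted_distribution_covers_observed_support(self, fitted):
        _true, counts, res = fitted
        dist = res.predicted_distribution()
        assert dist.probs.size > counts.max()
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_off_time_is_reciprocal_k_on(self, fitted):
        _true, _counts, res = fitted
        draws = np.exp(res.chains.pooled()[:, 0])
        assert res.params["off_time"] == pytest.approx(float(np.median(1.0 / draws)), rel=1e-9)

    def test_half_life_constructor_equivalent(self):
        counts = np.array([0, 1, 2, 3] * 50)
        m1 = TelegraphModel(counts, k_decay=K_DECAY)
        m2 = TelegraphModel(counts, half_life_hours=5.0)
        assert m1.k_decay == pytest.approx(m2.k_decay, rel=1e-12)
        with pytest.raises(ValueError):
            TelegraphModel(counts)
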