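"""Exact steady-state machinery: generator, CME null space, Beta-Poisson,
thinning and allele convolution."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from burstkit.model import (
    ModelSpec,
    RateParameters,
    SteadyStateDistribution,
    beta_poisson_pmf,
    build_generator,
    convolve_alleles,
    distribution_moments,
    steady_state,
    thin_distribution,
)

rate = hst.floats(min_value=1e-3, max_value=50.0)


class TestGenerator:
    @given(k_on=rate, k_off=rate, k_eject=rate, k_decay=rate)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_columns_sum_to_zero(self, k_on, k_off, k_eject, k_decay):
        spec = ModelSpec(2, 1, truncation=30)
        A = build_generator(spec, RateParameters.two_state(k_on, k_off, k_eject, k_decay))
        assert A.shape == (62, 62)
        assert np.abs(np.asarray(A.sum(axis=0))).max() < 1e-10
        off_diag = A.toarray() - np.diag(A.diagonal())
        assert (off_diag >= 0).all()

    def test_one_state_is_birth_death_chain(self):
        spec = ModelSpec(1, 1, truncation=3)
        A = build_generator(spec, RateParameters.one_state(1.0, 1.0)).toarray()
        expected = np.array(
            [
                [-1.0, 1.0, 0.0, 0.0],
                [1.0, -2.0, 2.0, 0.0],
                [0.0, 1.0, -3.0, 3.0],
                [0.0, 0.0, 1.0, -3.0],  # no ejection out of the boundary level
            ]
        )
        np.testing.assert_allclose(A, expected)

    def test_zero_ejection_only_switches_at_zero_counts(self):
        spec = ModelSpec(2, 1, truncation=5)
        A = build_generator(spec, RateParameters.two_state(0.3, 0.7, 0.0, 1.0)).toarray()
        # the m=0 block only exchanges probability between gene states
        assert A[2:, :2].sum() == 0.0

    def test_mismatched_rate_count_raises(self):
        spec = ModelSpec(3, 1, truncation=10)
        with pytest.raises(ValueError, match="switching rates"):
            build_generator(spec, RateParameters.two_state(1, 1, 1, 1))


class TestSteadyState:
    def test_one_state_is_poisson(self):
        d = steady_state(ModelSpec(1, 1), RateParameters.one_state(2.0, 1.0))
        assert d.probs[0] == pytest.approx(np.exp(-2), abs=1e-10)
        np.testing.assert_allclose(
            d.probs, st.poisson.pmf(np.arange(d.probs.size), 2.0), atol=1e-12
        )

    def test_two_state_matches_beta_poisson(self, two_state_spec, bursty_rates):
        d = steady_state(two_state_spec, bursty_rates)
        bp = beta_poisson_pmf(
            bursty_rates.alpha, bursty_rates.beta, bursty_rates.nu, np.arange(d.probs.size)
        )
        assert np.max(np.abs(d.probs - bp)) < 1e-6

    def test_zero_ejection_is_point_mass_at_zero(self, two_state_spec):
        d = steady_state(two_state_spec, RateParameters.two_state(0.3, 0.7, 0.0, 1.0))
        assert d.probs[0] == pytest.approx(1.0)

    def test_banded_and_nullspace_methods_agree(self, two_state_spec, bursty_rates):
        d1 = steady_state(two_state_spec, bursty_rates, method="banded")
        d2 = steady_state(two_state_spec, bursty_rates, method="nullspace")
        np.testing.assert_allclose(d1.probs, d2.probs, atol=1e-10)

    def test_invariant_to_larger_truncation(self, bursty_rates):
        d_auto = steady_state(ModelSpec(2, 1), bursty_rates)
        bigger = ModelSpec(2, 1, truncation=2 * d_auto.truncation)
        d_big = steady_state(bigger, bursty_rates)
        n = d_auto.probs.size
        np.testing.assert_allclose(d_auto.probs, d_big.probs[:n], atol=1e-9)

    @pytest.mark.parametrize(
        "n_states,state_rates",
        [(1, ()), (2, (1.2, 0.8)), (3, (0.7, 0.3, 1.5, 0.9))],
    )
    def test_probability_conservation(self, n_states, state_rates):
        d = steady_state(ModelSpec(n_states, 1), RateParameters(state_rates, 12.0, 1.0))
        assert abs(d.probs.sum() - 1.0) < 1e-8


class TestBetaPoisson:
    def test_zero_eject_rate(self):
        assert beta_poisson_pmf(3.0, 4.0, 0.0, 0) == 1.0
        assert beta_poisson_pmf(3.0, 4.0, 0.0, 5) == 0.0

    def test_uniform_mixing_closed_form(self):
        # alpha = beta = 1 mixes uniformly: P(0) = (1 - e^-nu) / nu
        assert beta_poisson_pmf(1.0, 1.0, 10.0, 0) == pytest.approx(
            (1 - np.exp(-10)) / 10, abs=1e-10
        )

    def test_against_hypergeometric_closed_form(self):
        # independent route: Gamma(a+n)Gamma(a+b)/(Gamma(a)Gamma(a+b+n))
        #                    * nu^n/n! * 1F1(a+n; a+b+n; -nu)
        from scipy.special import gammaln, hyp1f1

        a, b, nu, n = 2.0, 5.0, 8.0, 3
        ln = (
            gammaln(a + n) + gammaln(a + b) - gammaln(a) - gammaln(a + b + n)
            + n * np.log(nu) - gammaln(n + 1)
        )
        oracle = np.exp(ln) * hyp1f1(a + n, a + b + n, -nu)
        assert beta_poisson_pmf(a, b, nu, n) == pytest.approx(oracle, abs=1e-10)
        assert oracle == pytest.approx(0.148548153176, abs=1e-9)

    @pytest.mark.parametrize("a,b,nu", [(0.05, 20.0, 100.0), (2.0, 5.0, 8.0), (20.0, 0.05, 50.0)])
    def test_sums_to_one(self, a, b, nu):
        p = beta_poisson_pmf(a, b, nu, np.arange(0, 400))
        assert p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_poisson_pmf(-1.0, 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            beta_poisson_pmf(1.0, 1.0, -1.0, 0)


class TestMoments:
    def test_poisson_moments(self):
        d = steady_state(ModelSpec(1, 1), RateParameters.one_state(2.0, 1.0))
        mean, var = distribution_moments(d)
        assert mean == pytest.approx(2.0, abs=1e-8)
        assert var == pytest.approx(2.0, abs=1e-8)

    def test_two_state_mean_identity(self, rate_grid):
        # mean = nu * alpha / (alpha + beta)
        for a, b, nu in rate_grid[::5]:
            d = steady_state(ModelSpec(2, 1), RateParameters.two_state(a, b, nu, 1.0))
            mean, _ = distribution_moments(d)
            assert mean == pytest.approx(nu * a / (a + b), abs=1e-6)

    def test_variance_matches_direct_summation(self, rng):
        for _ in range(20):
            a, b, nu = rng.uniform(0.1, 5), rng.uniform(0.1, 5), rng.uniform(1, 40)
            d = steady_state(ModelSpec(2, 1), RateParameters.two_state(a, b, nu, 1.0))
            m = np.arange(d.probs.size)
            mu = float((m * d.probs).sum())
            var_direct = float((m**2 * d.probs).sum() - mu**2)
            _, var = distribution_moments(d)
            assert var == pytest.approx(var_direct, rel=1e-12)


class TestThinning:
    def test_identity_at_full_capture(self, two_state_spec, bursty_rates):
        d = steady_state(two_state_spec, bursty_rates)
        np.testing.assert_array_equal(thin_distribution(d, 1.0).probs, d.probs)

    def test_point_mass_stays_at_zero(self):
        d = SteadyStateDistribution(np.array([1.0, 0.0, 0.0]))
        assert thin_distribution(d, 0.3).probs[0] == pytest.approx(1.0)

    def test_poisson_thinning_closed_form(self):
        d = steady_state(ModelSpec(1, 1), RateParameters.one_state(2.0, 1.0))
        thinned = thin_distribution(d, 0.5)
        assert thinned.probs[0] == pytest.approx(np.exp(-1), abs=1e-10)

    @pytest.mark.parametrize(
        "n_states,state_rates",
        [(1, ()), (2, (1.2, 0.8)), (3, (0.7, 0.3, 1.5, 0.9))],
    )
    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5, 1.0])
    def test_thinning_equals_eject_rescaling(self, n_states, state_rates, p):
        """Binomial capture loss only rescales the eject rate, for any
        number of promoter states."""
        spec = ModelSpec(n_states, 1)
        nu = 12.0
        thinned = thin_distribution(steady_state(spec, RateParameters(state_rates, nu, 1.0)), p)
        direct = steady_state(spec, RateParameters(state_rates, p * nu, 1.0))
        n = max(thinned.probs.size, direct.probs.size)
        a = np.pad(thinned.probs, (0, n - thinned.probs.size))
        b = np.pad(direct.probs, (0, n - direct.probs.size))
        assert np.max(np.abs(a - b)) < 1e-8

    def test_invalid_probability_raises(self):
        d = SteadyStateDistribution(np.array([0.5, 0.5]))
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                thin_distribution(d, p)


class TestAlleleConvolution:
    def test_single_allele_is_identity(self, two_state_spec, bursty_rates):
        d = steady_state(two_state_spec, bursty_rates)
        np.testing.assert_array_equal(convolve_alleles(d, 1).probs, d.probs)

    def test_point_mass_shifts(self):
        d = SteadyStateDistribution(np.array([0.0, 1.0]))
        out = convolve_alleles(d, 2)
        assert out.probs[2] == pytest.approx(1.0)

    def test_poisson_additivity(self):
        d1 = steady_state(ModelSpec(1, 1), RateParameters.one_state(1.0, 1.0))
        two = convolve_alleles(d1, 2)
        assert two.probs[0] == pytest.approx(np.exp(-2), abs=1e-9)
        np.testing.assert_allclose(
            two.probs[:10], st.poisson.pmf(np.arange(10), 2.0), atol=1e-8
        )

    def test_mean_scales_with_allele_number(self, two_state_spec, bursty_rates):
        d = steady_state(two_state_spec, bursty_rates)
        for n in (2, 3):
            mean_n, _ = distribution_moments(convolve_alleles(d, n))
            assert mean_n == pytest.approx(n * d.mean, rel=1e-8)


class TestSerialization:
    def test_distribution_tsv_round_trip(self, two_state_spec, bursty_rates, tmp_path):
        d = steady_state(two_state_spec, bursty_rates)
        path = tmp_path / "dist.tsv"
        d.to_tsv(path)
        back = SteadyStateDistribution.from_tsv(path)
        np.testing.assert_allclose(back.probs, d.probs, atol=1e-15)
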