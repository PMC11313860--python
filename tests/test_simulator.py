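"""Stochastic simulation against the exact CME, and the fixture generators."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from burstkit.model import ModelSpec, RateParameters, steady_state
from burstkit.simulate import (
    SimulationConfig,
    gillespie_cell,
    gillespie_counts,
    rates_from_prior,
    simulate_correlated_pairs,
    simulate_dataset,
    simulate_decay_course,
)


def _tv(counts: np.ndarray, dist) -> float:
    hist = np.bincount(counts, minlength=dist.probs.size).astype(float)
    hist /= hist.sum()
    n = max(hist.size, dist.probs.size)
    a = np.pad(hist, (0, n - hist.size))
    b = np.pad(dist.probs, (0, n - dist.probs.size))
    return 0.5 * np.abs(a - b).sum()


class TestGillespie:
    def test_never_on_never_transcribes(self):
        rates = RateParameters.two_state(0.0, 1.0, 5.0, 1.0)
        cfg = SimulationConfig(spec=ModelSpec(2, 1), rates=rates, n_cells=200, seed=0)
        assert (gillespie_counts(cfg) == 0).all()

    def test_one_state_poisson_mean(self):
        nu = 2.0
        cfg = SimulationConfig(
            spec=ModelSpec(1, 1), rates=RateParameters.one_state(nu, 1.0),
            n_cells=50_000, seed=5,
        )
        draws = gillespie_counts(cfg)
        assert abs(draws.mean() - nu) < 3 * math.sqrt(nu / 50_000)

    def test_two_state_histogram_matches_cme(self):
        rates = RateParameters.two_state(1.0, 1.0, 10.0, 1.0)
        spec = ModelSpec(2, 1)
        cfg = SimulationConfig(spec=spec, rates=rates, n_cells=50_000, seed=9)
        assert _tv(gillespie_counts(cfg), steady_state(spec, rates)) < 0.02

    def test_three_state_histogram_matches_cme(self):
        rates = RateParameters((0.5, 0.3, 1.0, 0.8), 8.0, 1.0)
        spec = ModelSpec(3, 1)
        cfg = SimulationConfig(spec=spec, rates=rates, n_cells=50_000, seed=10)
        assert _tv(gillespie_counts(cfg), steady_state(spec, rates)) < 0.02

    def test_single_cell_draw_deterministic(self):
        cfg = SimulationConfig(
            spec=ModelSpec(2, 1), rates=RateParameters.two_state(1, 1, 5, 1),
            n_cells=1, seed=3,
        )
        assert gillespie_cell(cfg) == gillespie_cell(cfg)


@pytest.fixture(scope="module")
def truth():
    return rates_from_prior(4, seed=12)


@pytest.fixture(scope="module")
def base_cohort():
    # high-expression genes so the rank correlation is not destroyed by ties
    t = rates_from_prior(4, seed=8, mean_expression_range=(8.0, 20.0))
    return simulate_dataset(t, ModelSpec(2, n_alleles=2), 5000, seed=8)


class TestSimulateDataset:
    def test_seed_reproducibility(self, truth):
        spec = ModelSpec(2, n_alleles=2)
        a = simulate_dataset(truth, spec, 300, seed=1)
        b = simulate_dataset(truth, spec, 300, seed=1)
        assert a.matrix.equals(b.matrix)
        assert a.cell_info.equals(b.cell_info)

    def test_thinning_scales_means(self, truth):
        spec = ModelSpec(2, n_alleles=1)
        full = simulate_dataset(truth, spec, 4000, capture_yield=1.0, seed=2)
        thin = simulate_dataset(truth, spec, 4000, capture_yield=0.05, seed=2)
        ratio = thin.matrix.mean(axis=1) / full.matrix.mean(axis=1)
        assert np.allclose(ratio, 0.05, atol=0.03)

    def test_single_allele_histograms_match_cme(self):
        truth = rates_from_prior(2, seed=30, mean_expression_range=(2.0, 10.0))
        spec = ModelSpec(2, n_alleles=1)
        cohort = simulate_dataset(truth, spec, 50_000, capture_yield=1.0, seed=3)
        for gene, row in truth.iterrows():
            rates = RateParameters.two_state(
                row.k_on, row.k_off, row.k_eject, row.k_decay
            )
            counts = cohort.matrix.loc[gene].to_numpy()
            assert _tv(counts, steady_state(spec, rates)) < 0.02

    def test_truth_aligned_and_counts_nonnegative(self, truth):
        cohort = simulate_dataset(truth, ModelSpec(2, 2), 100, seed=4)
        assert list(cohort.matrix.index) == list(cohort.truth.index)
        assert (cohort.matrix.to_numpy() >= 0).all()
        assert cohort.matrix.to_numpy().dtype.kind == "i"


class TestCorrelatedPairs:
    @pytest.fixture()
    def base(self, base_cohort):
        return base_cohort

    def test_null_rho_within_band(self, base):
        g = base.genes
        out = simulate_correlated_pairs(base, [(g[0], g[1])], 0.0, seed=1)
        rho = spearmanr(out.matrix.loc[g[0]], out.matrix.loc[g[1]]).statistic
        assert abs(rho) < 0.03

    def test_target_rho_achieved(self, base):
        g = base.genes
        out = simulate_correlated_pairs(base, [(g[2], g[3])], 0.5, seed=2)
        rho = spearmanr(out.matrix.loc[g[2]], out.matrix.loc[g[3]]).statistic
        assert rho == pytest.approx(0.5, abs=0.07)

    def test_marginals_preserved(self, base):
        g = base.genes
        out = simulate_correlated_pairs(base, [(g[0], g[1])], 0.6, seed=3)
        for gene in (g[0], g[1]):
            before = np.sort(base.matrix.loc[gene].to_numpy())
            after = np.sort(out.matrix.loc[gene].to_numpy())
            # the copula reshuffles counts across cells, never changes them
            np.testing.assert_array_equal(before, after)

    def test_infeasible_rho_rejected(self, base):
        with pytest.raises(ValueError):
            simulate_correlated_pairs(base, [(base.genes[0], base.genes[1])], 1.0)


class TestDecayCourse:
    def test_noiseless_halving_after_normalization(self):
        half = 6.93
        table, _ = simulate_decay_course(
            np.array([half]), timepoints_hours=(0, half, 2 * half, 3 * half),
            noise_cv=0.0, n_replicates=1, seed=0,
        )
        spikes = table.index.str.startswith("ERCC-")
        scale = table.loc[spikes].sum(axis=0)
        conc = table.loc[~spikes].div(scale, axis=1)
        vals = conc.iloc[0].to_numpy()
        assert vals[1] / vals[0] == pytest.approx(0.5, rel=1e-9)

    def test_scale_factors_recoverable(self):
        table, scale = simulate_decay_course(
            np.array([2.0, 5.0]), noise_cv=0.1, n_replicates=1, seed=4
        )
        spikes = table.index.str.startswith("ERCC-")
        observed = table.loc[spikes].sum(axis=0)
        recovered = observed / observed.iloc[0] * scale.iloc[0]
        assert np.allclose(recovered.to_numpy(), scale.to_numpy(), rtol=0.01)

    def test_deterministic(self):
        a, sa = simulate_decay_course(np.array([3.0]), seed=7)
        b, sb = simulate_decay_course(np.array([3.0]), seed=7)
        assert a.equals(b) and sa.equals(sb)

    def test_timepoints_must_start_at_zero(self):
        with pytest.raises(ValueError):
            simulate_decay_course(np.array([3.0]), timepoints_hours=(1, 2, 4))


class TestRatesFromPrior:
    def test_respects_expression_window(self):
        truth = rates_from_prior(10, seed=5, mean_expression_range=(0.5, 10.0))
        mean = truth.k_eject / truth.k_decay * truth.k_on / (truth.k_on + truth.k_off)
        assert ((mean >= 0.5) & (mean <= 10.0)).all()

    def test_deterministic(self):
        assert rates_from_prior(5, seed=9).equals(rates_from_prior(5, seed=9))


class TestThinningCommutes:
    def test_simulate_then_thin_matches_rescaled_eject(self):
        """Thinning SSA counts at p is distributionally indistinguishable
        from simulating with the eject rate rescaled to p * nu."""
        from scipy.stats import chi2

        p = 0.3
        spec = ModelSpec(2, 1)
        full = RateParameters.two_state(1.0, 1.0, 20.0, 1.0)
        scaled = RateParameters.two_state(1.0, 1.0, p * 20.0, 1.0)
        a = gillespie_counts(SimulationConfig(spec=spec, rates=full, n_cells=50_000, seed=61))
        rng = np.random.default_rng(62)
        a = rng.binomial(a, p)
        b = gillespie_counts(SimulationConfig(spec=spec, rates=scaled, n_cells=50_000, seed=63))
        top = max(a.max(), b.max()) + 1
        ha = np.bincount(a, minlength=top).astype(float)
        hb = np.bincount(b, minlength=top).astype(float)
        # pool sparse bins, then two-sample chi-square
        keep = (ha + hb) >= 10
        ha = np.r_[ha[keep], ha[~keep].sum()]
        hb = np.r_[hb[keep], hb[~keep].sum()]
        k1, k2 = np.sqrt(hb.sum() / ha.sum()), np.sqrt(ha.sum() / hb.sum())
        stat = np.sum((k1 * ha - k2 * hb) ** 2 / (ha + hb))
        pval = chi2.sf(stat, df=ha.size - 1)
        assert pval > 0.01
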