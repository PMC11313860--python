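"""Self-contained validation studies exercising the whole pipeline.

Each study generates its own synthetic inputs with the package's simulator,
runs the corresponding analysis and returns scalar summaries.  They back
both the acceptance checks and the reproduction script; sizes default to
the desk-scale study conditions described in the methods note.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import qc as _qc
from .inference import TelegraphModel, TelegraphResults, mle_fit
from .model import (
    ModelSpec,
    RateParameters,
    beta_poisson_pmf,
    distribution_moments,
    steady_state,
    thin_distribution,
)
from .network import NetworkConfig, correlation_shift
from .selection import select_model
from .simulate import (
    SimulationConfig,
    gillespie_counts,
    rates_from_prior,
    simulate_correlated_pairs,
    simulate_dataset,
    simulate_decay_course,
)

__all__ = [
    "oracle_equivalence_study",
    "thinning_theorem_study",
    "ssa_cme_study",
    "moment_identity_study",
    "recovery_study",
    "yield_invariance_study",
    "model_selection_study",
    "halflife_study",
    "gene_qc_scan_study",
    "network_shift_study",
]

#: decay-scaled (alpha, beta, nu) grid used by the closed-form comparisons
ORACLE_GRID = [
    (a, b, nu)
    for a in (0.05, 0.3, 2.0, 8.0, 20.0)
    for b in (0.05, 0.5, 3.0, 20.0)
    for nu in (0.5, 8.0, 100.0)
][:50]


def oracle_equivalence_study(grid=None) -> float:
    """Max pointwise |CME steady state - Beta-Poisson| over the grid."""
    worst = 0.0
    spec = ModelSpec(2, n_alleles=1)
    for a, b, nu in grid or ORACLE_GRID:
        d = steady_state(spec, RateParameters.two_state(a, b, nu, 1.0))
        bp = beta_poisson_pmf(a, b, nu, np.arange(d.probs.size))
        worst = max(worst, float(np.max(np.abs(d.probs - bp))))
    return worst


THINNING_CASES = [(1, ()), (2, (1.2, 0.8)), (3, (0.7, 0.3, 1.5, 0.9))]


def thinning_theorem_study(nu: float = 12.0) -> float:
    """Max |thin(P(nu), p) - P(p nu)| over 1/2/3-state models and p grid."""
    worst = 0.0
    for n_states, sr in THINNING_CASES:
        spec = ModelSpec(n_states, 1)
        base = steady_state(spec, RateParameters(sr, nu, 1.0))
        for p in (0.05, 0.2, 0.5, 1.0):
            thinned = thin_distribution(base, p)
            direct = steady_state(spec, RateParameters(sr, p * nu, 1.0))
            n = max(thinned.probs.size, direct.probs.size)
            a = np.pad(thinned.probs, (0, n - thinned.probs.size))
            b = np.pad(direct.probs, (0, n - direct.probs.size))
            worst = max(worst, float(np.max(np.abs(a - b))))
    return worst


SSA_GRID = [
    (1, (), 2.0),
    (1, (), 15.0),
    (2, (1.0, 1.0), 10.0),
    (2, (0.1, 0.5), 30.0),
    (2, (5.0, 2.0), 8.0),
    (2, (0.3, 3.0), 50.0),
    (3, (0.5, 0.3, 1.0, 0.8), 8.0),
    (3, (0.2, 0.1, 0.4, 0.6), 20.0),
    (2, (2.0, 0.2, ), 5.0),
    (2, (0.05, 0.05), 12.0),
]


def ssa_cme_study(n_cells: int = 50_000, seed: int = 0) -> float:
    """Max total-variation distance between SSA histograms and the CME."""
    worst = 0.0
    for i, (n_states, sr, nu) in enumerate(SSA_GRID):
        spec = ModelSpec(n_states, 1)
        rates = RateParameters(sr, nu, 1.0)
        cfg = SimulationConfig(spec=spec, rates=rates, n_cells=n_cells, seed=seed + i)
        counts = gillespie_counts(cfg)
        dist = steady_state(spec, rates)
        hist = np.bincount(counts, minlength=dist.probs.size).astype(float)
        hist /= hist.sum()
        n = max(hist.size, dist.probs.size)
        a = np.pad(hist, (0, n - hist.size))
        b = np.pad(dist.probs, (0, n - dist.probs.size))
        worst = max(worst, float(0.5 * np.abs(a - b).sum()))
    return worst


def moment_identity_study(grid=None) -> float:
    """Max |mean(CME) - nu alpha / (alpha + beta)| over the grid."""
    worst = 0.0
    spec = ModelSpec(2, n_alleles=1)
    for a, b, nu in grid or ORACLE_GRID:
        d = steady_state(spec, RateParameters.two_state(a, b, nu, 1.0))
        mean, _ = distribution_moments(d)
        worst = max(worst, abs(mean - nu * a / (a + b)))
    return worst


def _simulate_prior_cohort(n_genes, n_cells, seed, capture_yield=1.0):
    k_decay = math.log(2.0) / 300.0  # 5-hour half-life
    truth = rates_from_prior(n_genes, k_decay=k_decay, seed=seed)
    spec = ModelSpec(2, n_alleles=2, capture_yield=capture_yield)
    cohort = simulate_dataset(truth, spec, n_cells, capture_yield=capture_yield,
                              seed=seed + 1)
    return truth, cohort


def _fit_cohort(cohort, truth, n_chains, n_samples, seed) -> dict[str, TelegraphResults]:
    results = {}
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(len(truth))
    for gi, gene in enumerate(truth.index):
        model = TelegraphModel(
            cohort.matrix.loc[gene].to_numpy(),
            k_decay=float(truth.loc[gene, "k_decay"]),
            n_alleles=2,
            gene=str(gene),
        )
        results[gene] = model.fit(
            n_chains=n_chains, n_samples=n_samples, seed=int(gene_seeds[gi]) & 0x7FFFFFFF
        )
    return results


def recovery_study(
    n_genes: int = 20,
    n_cells: int = 5000,
    n_chains: int = 4,
    n_samples: int = 50_000,
    seed: int = 0,
) -> dict:
    """Posterior recovery of prior-drawn ground-truth rates.

    Returns CI coverage over the free rates, the Spearman correlation of
    true vs posterior-median log10 k_on, the worst r-hat, and the fitted
    results/truth/cohort for downstream reuse.
    """
    from scipy.stats import spearmanr

    truth, cohort = _simulate_prior_cohort(n_genes, n_cells, seed)
    results = _fit_cohort(cohort, truth, n_chains, n_samples, seed + 1000)
    covered = 0
    total = 0
    true_kon, est_kon = [], []
    rhat_max = 0.0
    for gene, res in results.items():
        ci = res.conf_int()
        for name in ("k_on", "k_off", "k_eject"):
            lo, hi = ci.loc[name]
            if lo <= truth.loc[gene, name] <= hi:
                covered += 1
            total += 1
        true_kon.append(math.log10(truth.loc[gene, "k_on"]))
        est_kon.append(math.log10(res.params["k_on"]))
        rhat_max = max(rhat_max, res.posterior.rhat_max)
    rho = float(spearmanr(true_kon, est_kon).statistic)
    return {
        "coverage": covered / total,
        "kon_rank_corr": rho,
        "rhat_max": rhat_max,
        "results": results,
        "truth": truth,
        "cohort": cohort,
        "n_chains": n_chains,
        "n_samples": n_samples,
    }


def yield_invariance_study(recovery: dict, p: float = 0.2, seed: int = 77) -> dict:
    """Refit binomially thinned counts; only k_eject should move.

    Returns the median ratio of thinned to unthinned k_eject medians, and
    the fraction of genes whose k_on / k_off 95% credible intervals overlap
    between the two fits.
    """
    truth = recovery["truth"]
    cohort = recovery["cohort"]
    rng = np.random.default_rng(seed)
    thinned = pd.DataFrame(
        rng.binomial(cohort.matrix.to_numpy(), p),
        index=cohort.matrix.index, columns=cohort.matrix.columns,
    )
    ss = np.random.SeedSequence(seed + 1)
    gene_seeds = ss.generate_state(len(truth))
    ratios = []
    overlap_on = overlap_off = 0
    for gi, gene in enumerate(truth.index):
        model = TelegraphModel(
            thinned.loc[gene].to_numpy(),
            k_decay=float(truth.loc[gene, "k_decay"]),
            n_alleles=2,
            gene=str(gene),
        )
        res_thin = model.fit(
            n_chains=recovery["n_chains"], n_samples=recovery["n_samples"],
            seed=int(gene_seeds[gi]) & 0x7FFFFFFF,
        )
        res_full = recovery["results"][gene]
        ratios.append(res_thin.params["k_eject"] / res_full.params["k_eject"])
        for name, counter in (("k_on", "on"), ("k_off", "off")):
            lo_t, hi_t = res_thin.conf_int().loc[name]
            lo_f, hi_f = res_full.conf_int().loc[name]
            if max(lo_t, lo_f) < min(hi_t, hi_f):
                if counter == "on":
                    overlap_on += 1
                else:
                    overlap_off += 1
    n = len(truth)
    return {
        "keject_ratio_median": float(np.median(ratios)),
        "kon_overlap_frac": overlap_on / n,
        "koff_overlap_frac": overlap_off / n,
    }


def model_selection_study(n_reps: int = 20, n_cells: int = 5000, seed: int = 0) -> dict:
    """AIC model selection on clearly separated generating regimes.

    One-state (Poisson) data versus strongly bursty two-state data; returns
    the fraction of replicates in which AIC picks the generating model.
    """
    k_decay = 1.0
    one_rates = RateParameters.one_state(4.0, k_decay)
    bursty = RateParameters.two_state(0.05, 1.0, 50.0, k_decay)
    wins = {1: 0, 2: 0}
    for rep in range(n_reps):
        for true_states, rates in ((1, one_rates), (2, bursty)):
            spec = ModelSpec(true_states, 1)
            counts = gillespie_counts(
                SimulationConfig(spec=spec, rates=rates, n_cells=n_cells,
                                 seed=seed + 97 * rep + true_states)
            )
            lls = {
                s: mle_fit(counts, ModelSpec(s, n_alleles=1), k_decay, seed=seed)[1]
                for s in (1, 2, 3)
            }
            if select_model(lls).winner_aic == true_states:
                wins[true_states] += 1
    return {
        "one_state_accuracy": wins[1] / n_reps,
        "two_state_accuracy": wins[2] / n_reps,
    }


def halflife_study(n_genes: int = 100, noise_cv: float = 0.1, seed: int = 0) -> dict:
    """Half-life recovery on noiseless and noisy shutoff courses."""
    from .halflife import fit_decay, fit_decay_table, spikein_normalize

    t = np.array([0.0, 1, 2, 4, 8, 12, 24])
    # noiseless: the fit must reproduce parameters to optimizer tolerance
    worst_noiseless = 0.0
    for hl in (1.5, 4.0, 9.0):
        y = 3.0 * np.exp(-math.log(2.0) / hl * t)
        fit = fit_decay(y, t, fix_asym_zero=True)
        worst_noiseless = max(worst_noiseless, abs(fit.half_life - hl) / hl)
    # noisy: half-lives log-normal around 4 h, CV 0.1 noise, triplicates
    rng = np.random.default_rng(seed)
    true_half = np.exp(rng.normal(np.log(4.0), 0.6, n_genes))
    table, _ = simulate_decay_course(
        true_half, t, noise_cv=noise_cv, n_replicates=3, seed=seed + 1
    )
    course = spikein_normalize(table, np.repeat(t, 3), spikein_total_amount=1000.0)
    fits = fit_decay_table(course)
    rel = np.abs(fits["half_life_hours"].to_numpy() - true_half) / true_half
    return {
        "noiseless_max_rel_err": worst_noiseless,
        "noisy_median_rel_err": float(np.median(rel)),
    }


def gene_qc_scan_study(seed: int = 0) -> int:
    """Mismatches between the gene filter and an explicit brute-force scan
    on a 100-row table with exact boundary rows (must be 0)."""
    rng = np.random.default_rng(seed)
    n = 100
    names = ("k_on", "k_off", "k_eject", "burst_size")
    table = pd.DataFrame(
        {
            **{f"{nm}_median": rng.uniform(0.01, 1.0, n) for nm in names},
            **{f"{nm}_MAD": rng.uniform(0.0, 0.8, n) for nm in names},
            "expression": rng.uniform(0.0, 0.1, n),
        }
    )
    for nm in names:  # exact threshold rows: strict inequality must fail them
        table.loc[0, f"{nm}_median"] = 1.0
        table.loc[0, f"{nm}_MAD"] = 0.75
    table.loc[0, "expression"] = 0.5
    table.loc[1, "expression"] = 0.01
    out = _qc.filter_genes_table(table)
    mism = 0
    for i, row in table.iterrows():
        ok = all(
            row[f"{nm}_MAD"] / row[f"{nm}_median"] < 0.75 for nm in names
        ) and row["expression"] > 0.01
        if ok != bool(out.loc[i, "qc_pass"]):
            mism += 1
    return mism


def _network_truth(n_genes: int, seed: int) -> pd.DataFrame:
    """Moderately expressed, fast-switching genes for the network fixture."""
    rng = np.random.default_rng(seed)
    k_decay = math.log(2.0) / 60.0  # 1-hour half-life keeps simulation cheap
    k_on = rng.uniform(0.01, 0.05, n_genes)
    k_off = rng.uniform(0.02, 0.1, n_genes)
    mean = rng.uniform(5.0, 15.0, n_genes)
    k_eject = mean * k_decay * (k_on + k_off) / k_on
    return pd.DataFrame(
        {"k_on": k_on, "k_off": k_off, "k_eject": k_eject, "k_decay": k_decay},
        index=[f"gene{i:04d}" for i in range(n_genes)],
    )


def network_shift_study(
    n_runs: int = 20,
    n_pairs: int = 50,
    n_cells: int = 1500,
    rho: float = 0.5,
    seed: int = 0,
) -> dict:
    """Detection of perturbation-induced correlation loss vs replicates.

    Control and both replicates carry ``n_pairs`` disjoint gene pairs at
    Spearman ``rho``; the perturbation removes the coupling (shift -rho).
    The detection summary is the median absolute change of the monitored
    pairs (a centered MAD is blind to a coherent shift, and over the full
    pair universe any robust summary is insensitive to a 1% contamination).
    Returns the fraction of runs with a larger perturbation summary than
    replicate summary, plus the MAD of an identical-matrix comparison
    (exactly 0).
    """
    import warnings

    truth = _network_truth(2 * n_pairs, seed)
    pairs = [(f"gene{2*i:04d}", f"gene{2*i+1:04d}") for i in range(n_pairs)]
    config = NetworkConfig(depth_scale=30_000.0, detection_fraction=0.10)
    spec = ModelSpec(2, n_alleles=1)
    successes = 0
    for run in range(n_runs):
        base_seed = seed + 1000 * (run + 1)
        mats = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for role in range(4):  # ctrl, pert, rep1, rep2
                cohort = simulate_dataset(truth, spec, n_cells, seed=base_seed + role)
                target = 0.0 if role == 1 else rho
                cohort = simulate_correlated_pairs(
                    cohort, pairs, target, seed=base_seed + 10 + role
                )
                mats.append(cohort.matrix)
        pert, repl, _summary = correlation_shift(*mats, config)
        if pert.subset(pairs).mad_about_zero > repl.subset(pairs).mad_about_zero:
            successes += 1
    # identical-matrix control
    cohort = simulate_dataset(truth.iloc[:10], spec, 300, seed=seed + 5)
    m = cohort.matrix
    pert_id, _repl_id, _ = correlation_shift(m, m, m, m, config)
    return {
        "success_frac": successes / n_runs,
        "identical_mad": pert_id.mad_signed,
    }
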