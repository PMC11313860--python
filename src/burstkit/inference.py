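"""Bayesian fitting of telegraph models to per-gene mRNA count vectors.

The steady-state count histogram carries no absolute timescale, so the decay
rate is fixed at the independently measured value ``k_decay = ln 2 /
half-life`` and the remaining rates (one, three or five depending on the
number of promoter states) are sampled by an adaptive random-walk
Metropolis-Hastings algorithm in log-rate space.  Priors are broad
log-normals (means 0.01 / 0.1 / 0.05 per minute for the ON, OFF and eject
rates, coefficient of variation 10).  Capture loss is never modelled
explicitly: by the thinning theorem the inferred eject rate is simply the
yield-scaled true rate, while the switching rates are unaffected.

The user-facing surface follows the statsmodels convention: build a
:class:`TelegraphModel` from the data, call :meth:`~TelegraphModel.fit`, and
read estimates, uncertainties and diagnostics off the returned
:class:`TelegraphResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, model as _model
from .model import ModelSpec, RateParameters, SteadyStateDistribution, n_free_rates

__all__ = [
    "PriorSpec",
    "ChainSet",
    "ParamStats",
    "PosteriorSummary",
    "InsufficientDataError",
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "rhat",
    "summarize",
    "mle_fit",
    "TelegraphModel",
    "TelegraphResults",
]

LN2 = math.log(2.0)
RHAT_RERUN_THRESHOLD = 1.05


class InsufficientDataError(ValueError):
    """Too few informative cells to attempt a fit."""


def free_rate_names(n_states: int) -> list[str]:
    if n_states == 1:
        return ["k_eject"]
    if n_states == 2:
        return ["k_on", "k_off", "k_eject"]
    return ["f1", "b1", "f2", "b2", "k_eject"]


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-normal priors on the free rates (per minute).

    ``means`` are the prior means in the order ``state_rates + (k_eject,)``;
    the shared coefficient of variation ``cv`` sets the log-space width via
    ``sigma^2 = ln(1 + cv^2)`` and ``mu = ln(mean) - sigma^2 / 2``.
    """

    means: tuple[float, ...]
    cv: float = 10.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means):
            raise ValueError("prior means must be positive")
        if self.cv <= 0:
            raise ValueError("prior CV must be positive")

    @staticmethod
    def default(n_states: int = 2) -> "PriorSpec":
        """Broad defaults: ON-like rates 0.01/min, OFF-like 0.1, eject 0.05."""
        if n_states == 1:
            return PriorSpec((0.05,))
        if n_states == 2:
            return PriorSpec((0.01, 0.1, 0.05))
        return PriorSpec((0.01, 0.1, 0.01, 0.1, 0.05))

    @property
    def sigma_log(self) -> np.ndarray:
        s2 = math.log(1.0 + self.cv ** 2)
        return np.full(len(self.means), math.sqrt(s2))

    @property
    def mu_log(self) -> np.ndarray:
        s2 = math.log(1.0 + self.cv ** 2)
        return np.log(np.asarray(self.means)) - 0.5 * s2


@dataclass
class ChainSet:
    """Post-warmup MCMC draws of the free log-rates.

    ``samples`` has shape (n_chains, n_kept, n_free) in natural log of the
    rates (order ``state_rates + k_eject``); ``logliks`` holds the total
    data log-likelihood of each draw.
    """

    samples: np.ndarray
    logliks: np.ndarray
    param_names: list[str]
    n_samples: int
    n_warmup: int
    acceptance: np.ndarray
    seed: int
    spec: ModelSpec
    k_decay: float
    prior: PriorSpec

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains * n_kept, n_free)."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def index_of(self, parameter: str | int) -> int:
        if isinstance(parameter, str):
            return self.param_names.index(parameter)
        return int(parameter)


# ---------------------------------------------------------------------------
# likelihood and prior
# ---------------------------------------------------------------------------

def log_likelihood(dist: SteadyStateDistribution, counts) -> float:
    """Sum of log predicted probabilities at the observed counts.

    Equals ``n`` times the negative cross-entropy between the empirical
    histogram and the model pmf.  Probabilities below 1e-300 (including
    counts beyond the truncation) are floored with a warning.
    """
    counts = np.asarray(counts, dtype=int)
    p = dist.pmf(counts)
    if np.any(p < _kernels._LOG_FLOOR):
        warnings.warn("zero predicted probability at observed counts; floored at 1e-300")
        p = np.maximum(p, _kernels._LOG_FLOOR)
    return float(np.sum(np.log(p)))


def log_prior(prior: PriorSpec, rates) -> float:
    """Sum of log-normal log-densities over the free rates.

    ``rates`` may be a :class:`RateParameters` (free rates taken in order)
    or a plain vector of positive rates.
    """
    if isinstance(rates, RateParameters):
        x = np.array(list(rates.state_rates) + [rates.k_eject], dtype=float)
    else:
        x = np.asarray(rates, dtype=float)
    if x.size != len(prior.means):
        raise ValueError("rate vector does not match prior dimension")
    if np.any(x <= 0):
        return -math.inf
    mu, sig = prior.mu_log, prior.sigma_log
    lx = np.log(x)
    return float(
        np.sum(-lx - np.log(sig) - 0.5 * math.log(2 * math.pi) - 0.5 * ((lx - mu) / sig) ** 2)
    )


def _histogram(counts: np.ndarray) -> np.ndarray:
    return np.bincount(counts).astype(np.float64)


def _moment_init_log(
    n_states: int, prior: PriorSpec, mean_count: float, k_decay: float, n_alleles: int
) -> np.ndarray:
    """Start the chain at prior medians with the eject rate matched to the data mean."""
    x = prior.mu_log.copy()
    sr = np.exp(x[:-1])
    pi_on = float(_model.switching_stationary(n_states, tuple(sr))[-1])
    nu = max(mean_count, 0.05) / max(n_alleles * pi_on, 1e-6)
    x[-1] = math.log(max(nu * k_decay, 1e-8))
    return x


def run_mcmc(
    counts,
    spec: ModelSpec,
    prior: PriorSpec | None,
    k_decay: float,
    n_chains: int = 4,
    n_samples: int = 50_000,
    seed: int = 0,
    *,
    warmup_frac: float = 0.25,
    init_scale: float = 0.3,
    min_cells: int = 50,
    tail_tolerance: float = _model.TAIL_TOLERANCE,
    max_truncation: int = _model.MAX_TRUNCATION,
) -> ChainSet:
    """Sample the posterior of the free rates for one gene.

    Runs ``n_chains`` independent adaptive random-walk chains of
    ``n_samples`` iterations each, discarding the first ``warmup_frac``
    fraction; chains are seeded deterministically from ``seed`` so reruns
    are bit-identical.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise InsufficientDataError("empty count vector")
    if counts.max() == 0 and counts.size < min_cells:
        raise InsufficientDataError(
            f"all-zero counts with only {counts.size} cells (< {min_cells})"
        )
    if k_decay <= 0:
        raise ValueError("k_decay must be positive")
    if not 2 <= n_chains <= 8:
        raise ValueError("n_chains must be between 2 and 8")
    if prior is None:
        prior = PriorSpec.default(spec.n_states)
    if len(prior.means) != n_free_rates(spec.n_states):
        raise ValueError("prior dimension does not match the model")

    hist = _histogram(counts)
    n_warmup = int(round(warmup_frac * n_samples))
    mu_log = prior.mu_log
    sigma_log = prior.sigma_log
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(n_chains)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    base_init = _moment_init_log(
        spec.n_states, prior, float(counts.mean()), k_decay, spec.n_alleles
    )

    draws_all = []
    ll_all = []
    acc_all = []
    for c in range(n_chains):
        init = base_init + 0.3 * jitter_rng.standard_normal(mu_log.size)
        draws, lls, acc = _kernels.mh_chain(
            spec.n_states,
            hist,
            k_decay,
            mu_log,
            sigma_log,
            n_samples,
            n_warmup,
            int(chain_seeds[c]) & 0x7FFFFFFF,
            init,
            spec.n_alleles,
            init_scale,
            tail_tolerance,
            max_truncation,
        )
        draws_all.append(draws)
        ll_all.append(lls)
        acc_all.append(acc)

    return ChainSet(
        samples=np.stack(draws_all),
        logliks=np.stack(ll_all),
        param_names=free_rate_names(spec.n_states),
        n_samples=n_samples,
        n_warmup=n_warmup,
        acceptance=np.asarray(acc_all),
        seed=seed,
        spec=spec,
        k_decay=k_decay,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# convergence and summaries
# ---------------------------------------------------------------------------

def _psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor of a (n_chains, n) draw array."""
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains must contain at least 2 draws each")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        warnings.warn("zero within-chain variance; r-hat defined as 1")
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def rhat(chains: ChainSet | np.ndarray, parameter: str | int = 0, *, split: bool = True) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    With ``split=True`` (default) each chain is halved first, which also
    detects within-chain trends.  Values near 1 indicate convergence.
    """
    if isinstance(chains, ChainSet):
        arr = chains.samples[:, :, chains.index_of(parameter)]
    else:
        arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    if split:
        n = arr.shape[1] // 2
        if n < 2:
            raise ValueError("chains too short to split")
        arr = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
    return _psrf(arr)


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation from the median (unscaled)."""
    return float(np.median(np.abs(x - np.median(x))))


@dataclass(frozen=True)
class ParamStats:
    median: float
    mad: float
    ci_low: float
    ci_high: float


@dataclass
class PosteriorSummary:
    """Digest of one gene's posterior: point estimates, spread and diagnostics."""

    gene: str
    model_states: int
    n_cells: int
    expression: float
    params: dict[str, ParamStats]
    rhat: dict[str, float]
    loglik_at_median: float
    max_loglik: float
    acceptance: float
    mle: dict[str, float] | None = None
    mle_loglik: float | None = None
    k_decay: float = float("nan")

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values())

    def converged(self, threshold: float = RHAT_RERUN_THRESHOLD) -> bool:
        return self.rhat_max < threshold

    def to_row(self) -> dict:
        row: dict = {
            "gene": self.gene,
            "model_states": self.model_states,
            "n_cells": self.n_cells,
            "expression": self.expression,
        }
        for name, st in self.params.items():
            row[f"{name}_median"] = st.median
            row[f"{name}_MAD"] = st.mad
            row[f"{name}_ci_low"] = st.ci_low
            row[f"{name}_ci_high"] = st.ci_high
        row["rhat_max"] = self.rhat_max
        row["loglik"] = self.loglik_at_median
        row["acceptance"] = self.acceptance
        row["k_decay"] = self.k_decay
        return row


def _stats_from_draws(x: np.ndarray) -> ParamStats:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return ParamStats(float(np.median(x)), _mad(x), float(lo), float(hi))


def loglik_at(
    spec: ModelSpec, free_rates: np.ndarray, k_decay: float, counts: np.ndarray
) -> float:
    """Data log-likelihood at one free-rate vector (multi-allele model)."""
    hist = _histogram(np.asarray(counts, dtype=np.int64))
    sr = np.asarray(free_rates[:-1], dtype=float)
    return float(
        _kernels._loglik_hist(
            spec.n_states,
            sr,
            float(free_rates[-1]),
            k_decay,
            hist,
            spec.n_alleles,
            _model.TAIL_TOLERANCE,
            _model.MAX_TRUNCATION,
        )
    )


def summarize(
    chains: ChainSet,
    counts,
    *,
    gene: str = "",
    correct_yield: bool = False,
) -> PosteriorSummary:
    """Median/MAD/95% credible interval digests of a ChainSet.

    Derived quantities are computed per draw so their uncertainty reflects
    the joint posterior: ``burst_size = k_eject / k_off`` uses the paired
    (correlated) draws of the two rates, ``off_time = 1 / k_on``.  With
    ``correct_yield=True`` the eject-rate (and burst-size) draws are divided
    by the spec's capture yield before summarizing.
    """
    counts = np.asarray(counts, dtype=np.int64)
    pooled = chains.pooled()
    rates = np.exp(pooled)
    names = list(chains.param_names)
    spec = chains.spec
    if correct_yield and spec.capture_yield < 1.0:
        rates = rates.copy()
        rates[:, -1] /= spec.capture_yield

    stats = {name: _stats_from_draws(rates[:, i]) for i, name in enumerate(names)}
    if spec.n_states == 2:
        stats["off_time"] = _stats_from_draws(1.0 / rates[:, 0])
    if spec.n_states >= 2:
        stats["burst_size"] = _stats_from_draws(rates[:, -1] / rates[:, -2])

    rhats = {name: rhat(chains, name) for name in names}
    median_free = np.median(rates, axis=0)
    if correct_yield and spec.capture_yield < 1.0:
        median_free = median_free.copy()
        median_free[-1] *= spec.capture_yield  # likelihood lives on observed scale
    ll_median = loglik_at(spec, median_free, chains.k_decay, counts)
    return PosteriorSummary(
        gene=gene,
        model_states=spec.n_states,
        n_cells=int(counts.size),
        expression=float(counts.mean()),
        params=stats,
        rhat=rhats,
        loglik_at_median=ll_median,
        max_loglik=float(chains.logliks.max()),
        acceptance=float(chains.acceptance.mean()),
        k_decay=chains.k_decay,
    )


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def mle_fit(
    counts,
    spec: ModelSpec,
    k_decay: float,
    *,
    n_starts: int = 4,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-8, 1e3),
) -> tuple[RateParameters, float]:
    """Multi-start bounded maximum-likelihood estimate of the free rates.

    Optimizes in log-rate space with L-BFGS-B from the prior medians, a
    moment-matched start and random perturbations; returns the best optimum
    as :class:`RateParameters` together with its log-likelihood.
    """
    from scipy.optimize import minimize

    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise InsufficientDataError("empty count vector")
    hist = _histogram(counts)
    prior = PriorSpec.default(spec.n_states)
    nf = n_free_rates(spec.n_states)

    def neg_ll(x: np.ndarray) -> float:
        return -float(
            _kernels._loglik_hist(
                spec.n_states,
                np.exp(x[:-1]),
                math.exp(x[-1]),
                k_decay,
                hist,
                spec.n_alleles,
                _model.TAIL_TOLERANCE,
                _model.MAX_TRUNCATION,
            )
        )

    rng = np.random.default_rng(seed)
    base = _moment_init_log(spec.n_states, prior, float(counts.mean()), k_decay, spec.n_alleles)
    starts = [base, prior.mu_log]
    while len(starts) < n_starts:
        starts.append(base + rng.standard_normal(nf))
    lb, ub = math.log(bounds[0]), math.log(bounds[1])
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=[(lb, ub)] * nf)
        if res.success or math.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("MLE failed to converge from every start")
    x = np.exp(best.x)
    params = RateParameters(tuple(x[:-1]), float(x[-1]), k_decay)
    return params, -float(best.fun)


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class TelegraphModel:
    """A telegraph model bound to one gene's single-cell count vector.

    Parameters
    ----------
    counts
        Integer mRNA counts, one per cell (scRNA-seq or smRNA-FISH spots).
    k_decay
        Decay rate in min^-1; alternatively give ``half_life_hours``.
    n_states, n_alleles, capture_yield
        Structural model choices, see :class:`~burstkit.model.ModelSpec`.
    prior
        Log-normal rate priors; defaults to the broad standard priors.

    Examples
    --------
    >>> res = TelegraphModel(counts, half_life_hours=5.0).fit(seed=1)
    >>> res.params["burst_size"]
    """

    def __init__(
        self,
        counts,
        k_decay: float | None = None,
        *,
        half_life_hours: float | None = None,
        n_states: int = 2,
        n_alleles: int = 2,
        capture_yield: float = 1.0,
        prior: PriorSpec | None = None,
        gene: str = "",
    ) -> None:
        if (k_decay is None) == (half_life_hours is None):
            raise ValueError("give exactly one of k_decay or half_life_hours")
        if k_decay is None:
            if half_life_hours <= 0:
                raise ValueError("half_life_hours must be positive")
            k_decay = LN2 / (half_life_hours * 60.0)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.k_decay = float(k_decay)
        self.spec = ModelSpec(n_states=n_states, n_alleles=n_alleles, capture_yield=capture_yield)
        self.prior = prior if prior is not None else PriorSpec.default(n_states)
        self.gene = gene

    @classmethod
    def from_dataframe(
        cls, matrix: pd.DataFrame, gene: str, half_life_hours: float, **kwargs
    ) -> "TelegraphModel":
        """Build from a gene x cell count DataFrame and a half-life in hours."""
        if gene not in matrix.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return cls(
            matrix.loc[gene].to_numpy(),
            half_life_hours=half_life_hours,
            gene=gene,
            **kwargs,
        )

    def loglike(self, free_rates) -> float:
        """Log-likelihood at a vector of free rates (natural scale)."""
        return loglik_at(self.spec, np.asarray(free_rates, dtype=float), self.k_decay, self.counts)

    def fit(
        self,
        *,
        n_chains: int = 4,
        n_samples: int = 50_000,
        seed: int = 0,
        rerun_on_bad_rhat: bool = True,
        max_reruns: int = 3,
        compute_mle: bool = False,
        correct_yield: bool = False,
        **mcmc_kwargs,
    ) -> "TelegraphResults":
        """Posterior sampling; genes with r-hat >= 1.05 are rerun with a
        doubled budget until they converge (at most ``max_reruns`` times)."""
        budget = n_samples
        attempt = 0
        while True:
            chains = run_mcmc(
                self.counts, self.spec, self.prior, self.k_decay,
                n_chains=n_chains, n_samples=budget, seed=seed + attempt, **mcmc_kwargs,
            )
            summary = summarize(chains, self.counts, gene=self.gene, correct_yield=correct_yield)
            if summary.converged() or not rerun_on_bad_rhat or attempt >= max_reruns:
                break
            attempt += 1
            budget *= 2
        if compute_mle:
            params, ll = mle_fit(self.counts, self.spec, self.k_decay, seed=seed)
            summary.mle = dict(
                zip(free_rate_names(self.spec.n_states), list(params.state_rates) + [params.k_eject])
            )
            summary.mle_loglik = ll
            summary.max_loglik = max(summary.max_loglik, ll)
        return TelegraphResults(self, chains, summary)

    def fit_mle(self, **kwargs) -> tuple[RateParameters, float]:
        return mle_fit(self.counts, self.spec, self.k_decay, **kwargs)


class TelegraphResults:
    """Posterior fit of a :class:`TelegraphModel`.

    Exposes medians (``params``), MADs (``mad``), 95% credible intervals
    (``conf_int``), convergence diagnostics (``rhat``), a text ``summary()``
    and plotting / predictive helpers.
    """

    def __init__(self, model: TelegraphModel, chains: ChainSet, summary: PosteriorSummary):
        self.model = model
        self.chains = chains
        self.posterior = summary

    @property
    def params(self) -> pd.Series:
        return pd.Series({k: v.median for k, v in self.posterior.params.items()})

    @property
    def mad(self) -> pd.Series:
        return pd.Series({k: v.mad for k, v in self.posterior.params.items()})

    @property
    def rhat(self) -> pd.Series:
        return pd.Series(self.posterior.rhat)

    @property
    def llf(self) -> float:
        return self.posterior.loglik_at_median

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: (v.ci_low, v.ci_high) for k, v in self.posterior.params.items()},
            index=["2.5%", "97.5%"],
        ).T

    def predicted_distribution(self) -> SteadyStateDistribution:
        """Model pmf over cellular counts at the posterior median rates."""
        med = self.params
        names = self.chains.param_names
        rates = RateParameters(
            tuple(med[n] for n in names[:-1]), float(med[names[-1]]), self.model.k_decay
        )
        single = _model.steady_state(
            self.model.spec, rates, min_truncation=int(self.model.counts.max()) + 2
        )
        return _model.convolve_alleles(single, self.model.spec.n_alleles)

    def pointwise_loglik(self, n_draws: int = 400, seed: int = 0) -> np.ndarray:
        """Draws x cells matrix of per-cell log-likelihoods (for WAIC)."""
        pooled = np.exp(self.chains.pooled())
        rng = np.random.default_rng(seed)
        idx = rng.choice(pooled.shape[0], size=min(n_draws, pooled.shape[0]), replace=False)
        counts = self.model.counts
        out = np.empty((idx.size, counts.size))
        hist_len = int(counts.max()) + 1
        for r, i in enumerate(idx):
            free = pooled[i]
            sr = free[:-1]
            marg, ok = _kernels.steady_marginal(
                self.model.spec.n_states, sr, free[-1], self.model.k_decay,
                hist_len // self.model.spec.n_alleles + 2,
                _model.TAIL_TOLERANCE, _model.MAX_TRUNCATION,
            )
            p = marg
            for _ in range(self.model.spec.n_alleles - 1):
                p = np.convolve(p, marg)
            p = np.maximum(p, _kernels._LOG_FLOOR)
            lp = np.log(p)
            out[r] = np.where(counts < lp.size, lp[np.minimum(counts, lp.size - 1)],
                              math.log(_kernels._LOG_FLOOR))
        return out

    def summary(self) -> str:
        post = self.posterior
        lines = [
            f"Telegraph model fit ({post.model_states}-state, "
            f"{self.model.spec.n_alleles} allele(s))",
            f"gene: {post.gene or '-'}   cells: {post.n_cells}   "
            f"expression: {post.expression:.4g}",
            f"k_decay: {post.k_decay:.4g} /min (fixed)   "
            f"chains: {self.chains.n_chains} x {self.chains.n_samples} "
            f"(warmup {self.chains.n_warmup})",
            f"acceptance: {post.acceptance:.2f}   max r-hat: {post.rhat_max:.4f}   "
            f"loglik(median): {post.loglik_at_median:.2f}",
            "",
            f"{'parameter':>12} {'median':>12} {'MAD':>12} {'2.5%':>12} {'97.5%':>12}",
        ]
        for name, st in post.params.items():
            lines.append(
                f"{name:>12} {st.median:>12.5g} {st.mad:>12.5g} "
                f"{st.ci_low:>12.5g} {st.ci_high:>12.5g}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed count histogram with the fitted pmf overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        counts = self.model.counts
        dist = self.predicted_distribution()
        edges = np.arange(counts.max() + 2) - 0.5
        ax.hist(counts, bins=edges, density=True, alpha=0.5, label="observed")
        ax.plot(np.arange(dist.probs.size), dist.probs, "o-", ms=3, label="fit")
        ax.set_xlabel("mRNA count per cell")
        ax.set_ylabel("probability")
        ax.legend()
        return ax
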