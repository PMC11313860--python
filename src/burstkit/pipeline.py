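"""Batch drivers tying the per-gene model objects into whole-matrix runs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .inference import InsufficientDataError, TelegraphModel, TelegraphResults
from .selection import select_model

logger = logging.getLogger("burstkit")

__all__ = ["fit_genes", "select_models_for_gene", "fit_table_columns"]

fit_table_columns = [
    "gene", "model_states", "n_cells", "expression",
    "k_on_median", "k_on_MAD", "k_on_ci_low", "k_on_ci_high",
    "k_off_median", "k_off_MAD", "k_off_ci_low", "k_off_ci_high",
    "k_eject_median", "k_eject_MAD", "k_eject_ci_low", "k_eject_ci_high",
    "off_time_median", "off_time_MAD",
    "burst_size_median", "burst_size_MAD",
    "rhat_max", "loglik", "acceptance", "k_decay",
]


def _rename_derived(row: dict) -> dict:
    # expose off_time in minutes and log10 columns alongside the raw rates
    for name in ("k_on", "k_off", "k_eject", "burst_size"):
        med = row.get(f"{name}_median")
        if med is not None and med > 0:
            row[f"log10_{name}"] = np.log10(med)
    return row


def fit_genes(
    matrix: pd.DataFrame,
    half_lives_hours: pd.Series,
    *,
    n_states: int = 2,
    n_alleles: int | pd.Series = 2,
    n_chains: int = 4,
    n_samples: int = 50_000,
    seed: int = 0,
    capture_yield: float = 1.0,
    keep_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, TelegraphResults]]:
    """Fit the telegraph model to every gene with a known half-life.

    Genes missing from ``half_lives_hours`` are skipped with a log message
    (the decay rate anchors the timescale and cannot be inferred from a
    stationary histogram).  Per-gene seeds are derived deterministically
    from ``seed``.  Returns the long-format fit table (one row per gene);
    with ``keep_results=True`` also the underlying results objects.
    """
    rows = []
    results: dict[str, TelegraphResults] = {}
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(len(matrix.index))
    for gi, gene in enumerate(matrix.index):
        if gene not in half_lives_hours.index:
            logger.info("skipping %s: no measured half-life (decay rate required)", gene)
            continue
        alleles = int(n_alleles[gene]) if isinstance(n_alleles, pd.Series) else int(n_alleles)
        counts = matrix.loc[gene].to_numpy()
        model = TelegraphModel(
            counts,
            half_life_hours=float(half_lives_hours[gene]),
            n_states=n_states,
            n_alleles=alleles,
            capture_yield=capture_yield,
            gene=str(gene),
        )
        try:
            res = model.fit(
                n_chains=n_chains, n_samples=n_samples,
                seed=int(gene_seeds[gi]) & 0x7FFFFFFF,
            )
        except InsufficientDataError as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        rows.append(_rename_derived(res.posterior.to_row()))
        if keep_results:
            results[str(gene)] = res
    table = pd.DataFrame(rows)
    if keep_results:
        return table, results
    return table


def select_models_for_gene(
    counts,
    half_life_hours: float,
    *,
    n_alleles: int = 2,
    seed: int = 0,
    use_mcmc: bool = False,
    n_chains: int = 4,
    n_samples: int = 10_000,
    waic_draws: int = 300,
):
    """Fit 1-, 2- and 3-state models to one gene and compare them.

    By default the maximized likelihood comes from the multi-start MLE
    (fast); with ``use_mcmc=True`` posterior sampling is run as well, the
    best likelihood across draws and the MLE feeds AIC, and WAIC is
    computed from pointwise posterior log-likelihoods.
    """
    counts = np.asarray(counts, dtype=np.int64)
    max_ll: dict[int, float] = {}
    pointwise = {} if use_mcmc else None
    for s in (1, 2, 3):
        model = TelegraphModel(
            counts, half_life_hours=half_life_hours, n_states=s,
            n_alleles=n_alleles, gene="",
        )
        _params, ll = model.fit_mle(seed=seed)
        if use_mcmc:
            res = model.fit(n_chains=n_chains, n_samples=n_samples, seed=seed,
                            rerun_on_bad_rhat=False)
            ll = max(ll, res.posterior.max_loglik)
            pointwise[s] = res.pointwise_loglik(n_draws=waic_draws, seed=seed)
        max_ll[s] = ll
    return select_model(max_ll, pointwise)
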