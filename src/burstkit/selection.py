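"""Information-criterion comparison of 1-, 2- and 3-state fits.

AIC is computed from the best log-likelihood located by the sampler and the
MLE refinement; WAIC from the pointwise draws x cells log-likelihood matrix.
The free-parameter count excludes the fixed decay rate: one free rate for
the one-state (Poisson) model, three for the two-state telegraph model and
five for the three-state chain.  Ties are broken toward fewer states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ModelComparison", "aic", "waic", "select_model", "FREE_PARAMS"]

FREE_PARAMS = {1: 1, 2: 3, 3: 5}


def aic(max_loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 ln L."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * max_loglik


def waic(pointwise_loglik: np.ndarray) -> float:
    """Watanabe-Akaike information criterion from a draws x cells matrix.

    ``-2 (lppd - p_waic)`` with ``lppd = sum_c ln mean_d exp ll[d, c]`` and
    ``p_waic = sum_c var_d ll[d, c]`` (the variance-based effective
    parameter count); evaluated with log-sum-exp for stability.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, cells) matrix")
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


@dataclass
class ModelComparison:
    """Per-gene criterion values and winners across candidate state counts."""

    aic: dict[int, float]
    waic: dict[int, float | None]
    k: dict[int, int]
    winner_aic: int
    winner_waic: int | None

    def to_row(self, gene: str = "") -> dict:
        row: dict = {"gene": gene}
        for s in sorted(self.aic):
            row[f"aic{s}"] = self.aic[s]
        for s in sorted(self.waic):
            row[f"waic{s}"] = self.waic[s]
        row["winner_aic"] = self.winner_aic
        row["winner_waic"] = self.winner_waic
        return row


def _argmin_parsimonious(values: dict[int, float]) -> int:
    """State count minimizing the criterion; ties go to fewer states."""
    best_s, best_v = None, None
    for s in sorted(values):
        v = values[s]
        if best_v is None or v < best_v:
            best_s, best_v = s, v
    return best_s


def select_model(
    max_logliks: dict[int, float],
    pointwise_logliks: dict[int, np.ndarray] | None = None,
) -> ModelComparison:
    """Declare winning models by AIC (and WAIC when draws are supplied).

    ``max_logliks`` maps state count -> best log-likelihood found for that
    model fitted to the *same* counts; ``pointwise_logliks`` optionally maps
    state count -> draws x cells matrices for WAIC.
    """
    if not max_logliks:
        raise ValueError("no fits supplied")
    for s in max_logliks:
        if s not in FREE_PARAMS:
            raise ValueError(f"unknown model size {s}")
    aics = {s: aic(ll, FREE_PARAMS[s]) for s, ll in max_logliks.items()}
    waics: dict[int, float | None] = {s: None for s in max_logliks}
    winner_waic = None
    if pointwise_logliks:
        missing = set(max_logliks) - set(pointwise_logliks)
        if missing:
            raise ValueError(f"missing pointwise log-likelihoods for models {sorted(missing)}")
        waics = {s: waic(m) for s, m in pointwise_logliks.items()}
        winner_waic = _argmin_parsimonious({s: v for s, v in waics.items()})
    return ModelComparison(
        aic=aics,
        waic=waics,
        k={s: FREE_PARAMS[s] for s in max_logliks},
        winner_aic=_argmin_parsimonious(aics),
        winner_waic=winner_waic,
    )
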