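"""Perturbation-induced shifts of the single-cell coexpression network.

Counts are first depth-normalized per cell (fraction of the cell's reads,
rescaled to a common target depth and rounded back to integers), gene pairs
are restricted to those detected in at least 10% of cells in both compared
samples, and the coexpression of a pair is the Spearman rank correlation
across cells.  A perturbation's network effect is the distribution of
per-pair correlation changes, benchmarked against the same quantity
computed between two replicates of the unperturbed condition; the spread of
each distribution is summarized by its MAD (reported for both signed and
absolute changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "NetworkConfig",
    "CorrelationShiftTable",
    "depth_normalize",
    "eligible_pairs",
    "pair_correlations",
    "correlation_shift",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Depth target and detection threshold for the network comparison.

    ``depth_scale`` should be the mean reads per cell of the
    shallowest-sequenced sample (about 30,000 in typical 10x runs);
    ``detection_fraction`` is the minimum fraction of cells in which both
    genes of a pair must be detected, in each compared sample.
    """

    depth_scale: float = 30_000.0
    detection_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        if not (0.0 < self.detection_fraction < 1.0):
            raise ValueError("detection_fraction must lie in (0, 1)")


def depth_normalize(matrix: pd.DataFrame, config: NetworkConfig) -> pd.DataFrame:
    """Rescale each cell to the target depth, keeping counts integral.

    value = round(count / cell_total * depth_scale).  Cells with zero total
    counts should have been removed by QC and raise an error here.
    """
    totals = matrix.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = matrix.columns[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    scaled = matrix.to_numpy(dtype=float) / totals[None, :] * config.depth_scale
    return pd.DataFrame(
        np.rint(scaled).astype(np.int64), index=matrix.index, columns=matrix.columns
    )


def _detected_fraction(matrix: pd.DataFrame) -> pd.Series:
    return (matrix > 0).mean(axis=1)


def eligible_pairs(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, config: NetworkConfig
) -> list[tuple[str, str]]:
    """Unordered gene pairs detected in >= the threshold fraction of cells
    in *both* matrices (detection = nonzero normalized count)."""
    shared = matrix_a.index.intersection(matrix_b.index)
    fa = _detected_fraction(matrix_a.loc[shared])
    fb = _detected_fraction(matrix_b.loc[shared])
    ok = shared[(fa >= config.detection_fraction) & (fb >= config.detection_fraction)]
    genes = list(ok)
    return [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]


def _spearman_matrix(matrix: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """All-pairs Spearman correlations (midrank ties) for the listed genes."""
    sub = matrix.loc[genes].to_numpy(dtype=float)
    if len(genes) == 2:
        rho = spearmanr(sub[0], sub[1]).statistic
        corr = np.array([[1.0, rho], [rho, 1.0]])
    else:
        corr = spearmanr(sub, axis=1).statistic
    return pd.DataFrame(corr, index=genes, columns=genes)


def pair_correlations(
    matrix: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.Series:
    """Spearman rank correlation across cells for each requested pair."""
    genes = sorted({g for p in pairs for g in p})
    corr = _spearman_matrix(matrix, genes)
    return pd.Series({p: corr.loc[p[0], p[1]] for p in pairs})


@dataclass
class CorrelationShiftTable:
    """Per-pair correlations in two conditions and their differences."""

    table: pd.DataFrame  # columns: gene_a, gene_b, rho_1, rho_2, delta_rho
    label: str = ""

    @property
    def mad_signed(self) -> float:
        d = self.table["delta_rho"].to_numpy()
        return float(np.median(np.abs(d - np.median(d))))

    @property
    def mad_absolute(self) -> float:
        d = np.abs(self.table["delta_rho"].to_numpy())
        return float(np.median(np.abs(d - np.median(d))))

    @property
    def mad_about_zero(self) -> float:
        """Median |delta rho|: deviation from the no-change point.

        Coincides with the centered MAD when the change distribution is
        null-centered (as replicate comparisons are), but unlike it remains
        sensitive when a set of pairs shifts coherently.
        """
        return float(np.median(np.abs(self.table["delta_rho"].to_numpy())))

    def subset(self, pairs) -> "CorrelationShiftTable":
        """Restrict to a designated pair list (order-insensitive)."""
        wanted = {frozenset(p) for p in pairs}
        mask = [
            frozenset((a, b)) in wanted
            for a, b in zip(self.table["gene_a"], self.table["gene_b"])
        ]
        return CorrelationShiftTable(
            table=self.table.loc[mask].reset_index(drop=True), label=self.label
        )

    @property
    def n_pairs(self) -> int:
        return len(self.table)


def _shift_table(
    matrix_1: pd.DataFrame,
    matrix_2: pd.DataFrame,
    config: NetworkConfig,
    label: str,
) -> CorrelationShiftTable:
    pairs = eligible_pairs(matrix_1, matrix_2, config)
    if len(pairs) < 2:
        raise ValueError(f"fewer than 2 eligible gene pairs for comparison {label!r}")
    rho1 = pair_correlations(matrix_1, pairs)
    rho2 = pair_correlations(matrix_2, pairs)
    table = pd.DataFrame(
        {
            "gene_a": [p[0] for p in pairs],
            "gene_b": [p[1] for p in pairs],
            "rho_1": rho1.to_numpy(),
            "rho_2": rho2.to_numpy(),
            "delta_rho": (rho2 - rho1).to_numpy(),
        }
    )
    return CorrelationShiftTable(table=table, label=label)


def correlation_shift(
    matrix_ctrl: pd.DataFrame,
    matrix_pert: pd.DataFrame,
    matrix_rep1: pd.DataFrame,
    matrix_rep2: pd.DataFrame,
    config: NetworkConfig = NetworkConfig(),
    *,
    normalize: bool = True,
) -> tuple[CorrelationShiftTable, CorrelationShiftTable, pd.DataFrame]:
    """Perturbation-vs-control and replicate-vs-replicate correlation shifts.

    All four matrices are depth-normalized on the shared config (pass
    ``normalize=False`` if already normalized).  The eligibility filter is
    applied within each compared sample pair, so the two tables may cover
    different pair sets.  Returns the two shift tables and a one-row-per-
    comparison MAD summary (signed and absolute).
    """
    if normalize:
        matrix_ctrl = depth_normalize(matrix_ctrl, config)
        matrix_pert = depth_normalize(matrix_pert, config)
        matrix_rep1 = depth_normalize(matrix_rep1, config)
        matrix_rep2 = depth_normalize(matrix_rep2, config)
    pert = _shift_table(matrix_ctrl, matrix_pert, config, "perturbation_vs_control")
    repl = _shift_table(matrix_rep1, matrix_rep2, config, "replicate_vs_replicate")
    summary = pd.DataFrame(
        [
            {"comparison": t.label, "n_pairs": t.n_pairs,
             "mad_signed": t.mad_signed, "mad_absolute": t.mad_absolute,
             "mad_about_zero": t.mad_about_zero}
            for t in (pert, repl)
        ]
    )
    return pert, repl, summary
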