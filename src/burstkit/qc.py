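"""Two-stage quality control.

Stage one removes low-quality cells from the raw matrix by clipping the
extreme tails of the per-cell feature-count and total-count distributions
(keeping the central ~90% of each) and discarding cells with a high
mitochondrial read fraction.  Stage two filters the *inferred* rates: a
gene is kept only when every rate's relative posterior spread
(MAD / median) is below 0.75 for k_on, k_off, k_eject and burst size, and
its mean expression exceeds 0.01 counts per cell.  Inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSummary

__all__ = [
    "CellQCConfig",
    "GeneQCRecord",
    "GeneQCThresholds",
    "filter_cells",
    "mito_fraction",
    "filter_genes",
    "filter_genes_table",
]


@dataclass(frozen=True)
class CellQCConfig:
    """Cell-level filtering thresholds.

    ``central_fraction`` is the central quantile band retained for both the
    feature-count and total-count covariates (0.90 keeps the 5th-95th
    percentile band); ``mito_max`` is the strict upper bound on the
    mitochondrial fraction (0.05 by default, 0.075 for permissive runs).
    """

    central_fraction: float = 0.90
    mito_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.central_fraction < 1.0):
            raise ValueError("central_fraction must lie in (0, 1)")
        if not (0.0 < self.mito_max < 1.0):
            raise ValueError("mito_max must lie in (0, 1)")


def mito_fraction(
    matrix: pd.DataFrame, prefixes: tuple[str, ...] = ("MT-", "mt-")
) -> pd.Series:
    """Per-cell fraction of counts mapping to mitochondrial genes.

    Mitochondrial features are recognized by name prefix (human ``MT-``,
    mouse ``mt-`` by default; configurable).
    """
    names = matrix.index.astype(str)
    is_mito = np.zeros(len(names), dtype=bool)
    for p in prefixes:
        is_mito |= names.str.startswith(p)
    totals = matrix.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts")
    return matrix.loc[is_mito].sum(axis=0) / totals


def filter_cells(
    matrix: pd.DataFrame,
    cell_info: pd.DataFrame,
    config: CellQCConfig = CellQCConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain cells in the central quantile band of both covariates.

    ``cell_info`` must carry ``feature_counts``, ``total_counts`` and
    ``mito_fraction`` rows aligned to the matrix columns.  A cell is kept
    when it lies inside the central band for *both* count covariates
    (band edges inclusive) and its mitochondrial fraction is strictly below
    ``mito_max``.  Returns the filtered matrix and a per-criterion report.
    """
    if not matrix.columns.equals(cell_info.index):
        cell_info = cell_info.reindex(matrix.columns)
        if cell_info.isna().any().any():
            raise ValueError("cell_info is not aligned to the matrix columns")
    q_lo = (1.0 - config.central_fraction) / 2.0
    q_hi = 1.0 - q_lo
    keep = pd.Series(True, index=matrix.columns)
    report_rows = []
    for cov in ("feature_counts", "total_counts"):
        x = cell_info[cov].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [q_lo, q_hi])
        ok = (x >= lo) & (x <= hi)
        report_rows.append({"criterion": cov, "removed": int((~ok).sum()),
                            "lower": lo, "upper": hi})
        keep &= ok
    mito_ok = cell_info["mito_fraction"].to_numpy(dtype=float) < config.mito_max
    report_rows.append({"criterion": "mito_fraction", "removed": int((~mito_ok).sum()),
                        "lower": 0.0, "upper": config.mito_max})
    keep &= mito_ok
    if not keep.any():
        raise ValueError(
            "cell QC removed every cell; relax central_fraction or mito_max"
        )
    report = pd.DataFrame(report_rows)
    report.loc[len(report)] = {"criterion": "retained", "removed": int(keep.sum()),
                               "lower": np.nan, "upper": np.nan}
    return matrix.loc[:, keep], report


@dataclass(frozen=True)
class GeneQCThresholds:
    """Gene-level rate-quality thresholds (strict inequalities)."""

    max_mad_ratio: float = 0.75
    min_expression: float = 0.01


@dataclass(frozen=True)
class GeneQCRecord:
    """Per-gene rate-quality ratios and the resulting pass flag."""

    gene: str
    k_on_ratio: float
    k_off_ratio: float
    k_eject_ratio: float
    burst_size_ratio: float
    expression: float
    passed: bool


def _ratio(summary: PosteriorSummary, name: str) -> float:
    st = summary.params[name]
    return st.mad / st.median


def filter_genes(
    summaries: list[PosteriorSummary],
    thresholds: GeneQCThresholds = GeneQCThresholds(),
) -> list[GeneQCRecord]:
    """Flag genes whose posteriors are tight enough to interpret.

    Pass requires MAD/median < 0.75 (strict) for k_on, k_off, k_eject and
    burst size *and* expression > 0.01 (strict).  The predicate is pure:
    record order matches input order and repeated application is a no-op.
    """
    records = []
    for s in summaries:
        try:
            ratios = {name: _ratio(s, name) for name in
                      ("k_on", "k_off", "k_eject", "burst_size")}
        except KeyError as exc:
            raise ValueError(f"summary for {s.gene!r} lacks parameter {exc}") from exc
        passed = (
            all(r < thresholds.max_mad_ratio for r in ratios.values())
            and s.expression > thresholds.min_expression
        )
        records.append(
            GeneQCRecord(
                gene=s.gene,
                k_on_ratio=ratios["k_on"],
                k_off_ratio=ratios["k_off"],
                k_eject_ratio=ratios["k_eject"],
                burst_size_ratio=ratios["burst_size"],
                expression=s.expression,
                passed=passed,
            )
        )
    return records


def filter_genes_table(
    table: pd.DataFrame,
    thresholds: GeneQCThresholds = GeneQCThresholds(),
) -> pd.DataFrame:
    """Gene-level filter applied to a fit-output table.

    Expects columns ``{rate}_median`` and ``{rate}_MAD`` for k_on, k_off,
    k_eject and burst_size plus ``expression``; returns the table with the
    per-rate ratios and a boolean ``qc_pass`` column appended.
    """
    out = table.copy()
    ok = pd.Series(True, index=table.index)
    for name in ("k_on", "k_off", "k_eject", "burst_size"):
        med, mad = f"{name}_median", f"{name}_MAD"
        if med not in table.columns or mad not in table.columns:
            raise ValueError(f"table lacks columns {med!r}/{mad!r}")
        ratio = table[mad] / table[med]
        out[f"{name}_mad_ratio"] = ratio
        ok &= ratio < thresholds.max_mad_ratio
    if "expression" not in table.columns:
        raise ValueError("table lacks an 'expression' column")
    ok &= table["expression"] > thresholds.min_expression
    out["qc_pass"] = ok
    return out
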