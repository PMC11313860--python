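"""Depth normalization for comparing bursting parameters across cell types.

scRNA-seq yield scales with sequencing depth, and by the thinning theorem
the inferred eject rate (hence the burst size) scales with yield.  To
compare expression or burst size across samples sequenced to different
depths, each value is rescaled by that sample's mean reads per cell
relative to the average across the compared cell types:

    normalized = value / reads_per_cell * mean(reads_per_cell across types)

Reads per cell is taken as the post-QC mean total counts per cell of the
sample, since the fits are computed on the QC-passed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CellTypeDepthTable", "normalize_value", "normalize_table"]


@dataclass(frozen=True)
class CellTypeDepthTable:
    """Mean reads per cell for each compared cell type."""

    reads_per_cell: pd.Series  # index: cell type

    def __post_init__(self) -> None:
        if (self.reads_per_cell <= 0).any():
            raise ValueError("reads per cell must be positive")

    @property
    def average(self) -> float:
        return float(self.reads_per_cell.mean())


def normalize_value(value, reads_per_cell: float, avg_reads_across_types: float):
    """Depth-normalize an expression or burst-size value (linear in value)."""
    if np.any(np.asarray(reads_per_cell) <= 0) or np.any(np.asarray(avg_reads_across_types) <= 0):
        raise ValueError("read depths must be positive")
    return value / reads_per_cell * avg_reads_across_types


def normalize_table(
    table: pd.DataFrame,
    depth: CellTypeDepthTable,
    cell_type_column: str = "cell_type",
    columns: tuple[str, ...] = ("expression", "burst_size_median"),
) -> pd.DataFrame:
    """Apply the depth normalization to selected columns of a fit table.

    Each row's cell type (from ``cell_type_column``) selects its reads per
    cell; normalized values are appended as ``<column>_depthnorm``.
    """
    out = table.copy()
    rpc = table[cell_type_column].map(depth.reads_per_cell)
    if rpc.isna().any():
        missing = sorted(set(table[cell_type_column]) - set(depth.reads_per_cell.index))
        raise ValueError(f"no depth entry for cell type(s) {missing}")
    for col in columns:
        if col in table.columns:
            out[f"{col}_depthnorm"] = normalize_value(
                table[col].to_numpy(dtype=float), rpc.to_numpy(dtype=float), depth.average
            )
    return out
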