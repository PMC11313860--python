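"""Readers and writers for the count-matrix and table formats.

Supports the 10x-style MatrixMarket triplet directory (``matrix.mtx`` plus
``features.tsv``/``genes.tsv`` and ``barcodes.tsv``, optionally gzipped),
dense gene x cell TSV/CSV matrices, smRNA-FISH spot-count CSVs, half-life
and allele-number tables.  Output tables are TSV with one ``#``-prefixed
metadata header line carrying the tool version, the seed and a config hash
so runs are auditable and diff-friendly.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_count_matrix",
    "write_mtx_dir",
    "read_fish_counts",
    "read_halflives",
    "read_alleles",
    "write_table",
    "read_table",
    "config_hash",
]

TOOL = "burstkit"
VERSION = "0.1.0"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _maybe_gz(path: Path) -> Path | None:
    for cand in (path, path.with_name(path.name + ".gz")):
        if cand.exists():
            return cand
    return None


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_mtx_dir(path: Path) -> pd.DataFrame:
    mtx = _maybe_gz(path / "matrix.mtx")
    if mtx is None:
        raise FormatError(f"no matrix.mtx[.gz] in {path}")
    feat = None
    for name in ("features.tsv", "genes.tsv"):
        feat = _maybe_gz(path / name)
        if feat is not None:
            break
    if feat is None:
        raise FormatError(f"no features.tsv[.gz] or genes.tsv[.gz] in {path}")
    bc = _maybe_gz(path / "barcodes.tsv")
    if bc is None:
        raise FormatError(f"no barcodes.tsv[.gz] in {path}")

    with _open_text(mtx) as fh:
        try:
            m = scipy.io.mmread(fh)
        except Exception as exc:
            raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    m = scipy.sparse.csr_matrix(m)
    with _open_text(feat) as fh:
        features = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_text(bc) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if m.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{mtx}: matrix is {m.shape} but {len(features)} features x "
            f"{len(barcodes)} barcodes were listed"
        )
    dense = np.asarray(m.todense())
    if not np.allclose(dense, np.rint(dense)):
        raise FormatError(f"{mtx}: non-integer entries in count matrix")
    return pd.DataFrame(dense.astype(np.int64), index=features, columns=barcodes)


def read_count_matrix(path) -> pd.DataFrame:
    """Gene x cell integer count matrix from an MTX directory or dense table.

    ``path`` may be a 10x-style triplet directory or a TSV/CSV file with
    gene rows (first column = gene names, remaining columns = cells).
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if ".csv" in path.suffixes or path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.rint(arr)):
        raise FormatError(f"{path}: matrix entries must be integers")
    if (arr < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_mtx_dir(matrix: pd.DataFrame, path) -> None:
    """Write a gene x cell matrix as a 10x-style MTX triplet directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.coo_matrix(matrix.to_numpy())
    with open(path / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, sp, field="integer")
    (path / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.index))
    (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.columns))


def read_fish_counts(path) -> np.ndarray:
    """Per-cell smRNA-FISH spot counts from a (cell, count) CSV.

    The returned vector feeds the same fitting pipeline as scRNA counts
    (FISH counts are unthinned, so the inferred eject rate is on the true
    molecular scale).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no rows")
    col = df.columns[-1]
    vals = df[col].to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(vals, np.rint(vals)):
        raise FormatError(f"{path}: counts must be integers")
    if (vals < 0).any():
        raise FormatError(f"{path}: negative counts")
    return vals.astype(np.int64)


def read_halflives(path) -> pd.Series:
    """Per-gene mRNA half-lives in hours from a (gene, half_life) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gene, half-life (hours)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        raise FormatError(f"{path}: half-lives must be positive")
    return s


def read_alleles(path) -> pd.Series:
    """Per-gene allele numbers from a (gene, n_alleles) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=int), index=df.iloc[:, 0].astype(str))
    if (s < 1).any():
        raise FormatError(f"{path}: allele numbers must be >= 1")
    return s


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: dict | None = None, *, index: bool = True) -> None:
    """TSV writer with a single ``#`` metadata header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"tool": TOOL, "version": VERSION}
    if config:
        meta["config_hash"] = config_hash(config)
        if "seed" in config:
            meta["seed"] = config["seed"]
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n"
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(header + buf.getvalue())


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (metadata line skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
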