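"""Expression-matrix container, readers/writers, and preprocessing.

Matrices are gene x cell throughout: genes as rows, cells as columns,
identifiers carried alongside the dense float64 array.  Three spaces are
tracked: raw ``counts``, library-normalised ``cpm`` (every cell column sums
to 1e6), and ``log_cpm`` (natural log of 1 + CPM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

SPACES = ("counts", "cpm", "log_cpm")


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be parsed as an expression matrix."""


@dataclass
class ExpressionMatrix:
    """A gene x cell expression matrix with identifiers and a space flag.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Non-negative, finite expression values.
    gene_ids, cell_ids : list of str
        Row and column identifiers, in order.
    space : {"counts", "cpm", "log_cpm"}
        Which scale the values live on.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    space: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")
        if (self.values < 0).any():
            raise ValueError("values contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.space
        )


def load_matrix(path: str | Path, format: str = "csv") -> ExpressionMatrix:
    """Read an expression matrix in counts space.

    ``csv``/``tsv``: genes as rows, first column gene ids, header row of cell
    ids.  ``mtx_10x``: Matrix-Market file with ``genes.tsv`` (or
    ``features.tsv``) and ``barcodes.tsv`` sidecars in the same directory,
    1-based coordinates per the 10x convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixFormatError(
                f"{path}: non-finite value at data line {bad[0] + 2}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise MatrixFormatError(
                f"{path}: negative value at data line {bad[0] + 2}"
            )
        return ExpressionMatrix(values, list(df.index), list(df.columns), "counts")
    if format == "mtx_10x":
        genes_file = _first_existing(path.parent, ["genes.tsv", "features.tsv"])
        barcodes_file = path.parent / "barcodes.tsv"
        if genes_file is None or not barcodes_file.exists():
            raise FileNotFoundError(
                f"missing genes/features or barcodes sidecar next to {path}"
            )
        try:
            mat = spio.mmread(path)
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        genes = pd.read_csv(genes_file, sep="\t", header=None)
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)
        values = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64)
        if (values < 0).any():
            raise MatrixFormatError(f"{path}: negative stored entry")
        return ExpressionMatrix(
            values, list(genes.iloc[:, 0]), list(barcodes.iloc[:, 0]), "counts"
        )
    raise ValueError(f"unknown format {format!r}")


def save_matrix(m: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a matrix in the same orientation it is read: genes x cells."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path, sep=sep)
    elif format == "mtx_10x":
        spio.mmwrite(str(path), sparse.coo_matrix(m.values))
        pd.Series(m.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(m.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def _first_existing(directory: Path, names: list[str]) -> Path | None:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    return None


def filter_empty(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop all-zero gene rows and all-zero cell columns.

    The relative order of survivors is preserved; dropped identifiers are
    logged.  Idempotent.  Raises if nothing survives.
    """
    if m.space != "counts":
        raise ValueError("filter_empty expects a counts-space matrix")
    gene_keep = m.values.sum(axis=1) > 0
    cell_keep = m.values.sum(axis=0) > 0
    if not gene_keep.any() or not cell_keep.any():
        raise ValueError("filtering removed every gene or every cell")
    dropped_genes = [g for g, k in zip(m.gene_ids, gene_keep) if not k]
    dropped_cells = [c for c, k in zip(m.cell_ids, cell_keep) if not k]
    if dropped_genes:
        logger.info("filter_empty: dropped %d all-zero genes", len(dropped_genes))
    if dropped_cells:
        logger.info("filter_empty: dropped %d all-zero cells", len(dropped_cells))
    return ExpressionMatrix(
        m.values[np.ix_(gene_keep, cell_keep)],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        "counts",
    )


def normalize_library(m: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Scale each cell column to a fixed library size (counts-per-million)."""
    if m.space != "counts":
        raise ValueError("normalize_library expects a counts-space matrix")
    colsums = m.values.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("all-zero cell column; run filter_empty first")
    out = m.values * (scale / colsums)
    return ExpressionMatrix(out, list(m.gene_ids), list(m.cell_ids), "cpm")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform with a pseudocount of one: x -> log(1 + x)."""
    if m.space != "cpm":
        raise ValueError("log_transform expects a cpm-space matrix")
    return ExpressionMatrix(
        np.log1p(m.values), list(m.gene_ids), list(m.cell_ids), "log_cpm"
    )


def preprocess(
    m: ExpressionMatrix, log: bool = True, scale: float = 1e6
) -> ExpressionMatrix:
    """filter_empty -> normalize_library -> (optionally) log_transform."""
    out = normalize_library(filter_empty(m), scale=scale)
    return log_transform(out) if log else out
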