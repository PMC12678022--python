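"""Core in-memory containers shared across the pipeline.

The spine of every analysis is a pair of aligned objects:

* a *cell table* — a :class:`pandas.DataFrame` with one row per segmented
  cell, carrying its centroid (μm, image convention: origin top-left, y
  increasing downward), area, sample and condition labels, and optionally a
  ``cell_type`` annotation;
* a :class:`CountMatrix` — genes × cells raw integer counts plus, after
  normalization, a real-valued ``normalized`` layer.

Cells appear in the same order in both objects; every operation that
subsets one subsets the other through :meth:`CountMatrix.subset_cells`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Columns every cell table must carry.
CELL_COLUMNS = ("cell_id", "x_um", "y_um", "area_um2", "sample_id", "condition")


class AlignmentError(ValueError):
    """Cell metadata and count matrix do not describe the same cells."""


def validate_cell_table(cells: pd.DataFrame, require_type: bool = False) -> pd.DataFrame:
    """Check the cell-table schema and invariants; returns the table unchanged.

    Parameters
    ----------
    cells
        Candidate cell table.
    require_type
        Additionally require a fully populated ``cell_type`` column
        (needed by the spatial modules).
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_ids: {dups[:5]}")
    coords = cells[["x_um", "y_um"]].to_numpy(float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite cell coordinates")
    if len(cells) and not (cells["area_um2"].to_numpy(float) > 0).all():
        raise ValueError("cell areas must be positive")
    if require_type:
        if "cell_type" not in cells.columns or cells["cell_type"].isna().any():
            raise ValueError("cell table must carry a cell_type annotation for every cell")
    return cells


@dataclass
class CountMatrix:
    """Genes × cells expression matrix with raw and normalized layers.

    ``raw`` holds nonnegative integer counts (sparse CSR, genes as rows).
    ``normalized`` is filled by :func:`dermniche.qc.normalize_counts` and is
    a dense float array of the same shape; ``scale_factor`` records the
    per-cell total the normalization rescaled to.
    """

    genes: pd.Index
    cells: pd.Index
    raw: sp.csr_matrix
    normalized: Optional[np.ndarray] = None
    scale_factor: Optional[float] = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell_id")
        self.raw = sp.csr_matrix(self.raw)
        if self.raw.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"raw shape {self.raw.shape} != (genes={len(self.genes)}, cells={len(self.cells)})"
            )
        if self.raw.nnz and self.raw.data.min() < 0:
            raise ValueError("raw counts must be nonnegative")
        if self.genes.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.cells.duplicated().any():
            raise ValueError("duplicate cell ids")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.raw.shape:
                raise ValueError("normalized layer shape mismatch")

    # -- convenience -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_totals(self) -> np.ndarray:
        """Total raw counts per cell."""
        return np.asarray(self.raw.sum(axis=0)).ravel()

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer absent; run normalize_counts first")
        return self.normalized

    def cell_indexer(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Positions of ``cell_ids`` in the matrix, validating membership."""
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            bad = [c for c, i in zip(cell_ids, idx) if i < 0]
            raise AlignmentError(f"cell ids not in matrix: {bad[:5]}")
        return idx

    def gene_row(self, gene: str, layer: str = "normalized") -> np.ndarray:
        """Dense expression vector of one gene across cells."""
        if gene not in self.genes:
            raise KeyError(f"unknown gene: {gene!r}")
        i = self.genes.get_loc(gene)
        if layer == "raw":
            return np.asarray(self.raw[i].todense()).ravel()
        return self.require_normalized()[i]

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix restricted to cell positions ``keep`` (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            genes=self.genes,
            cells=self.cells[keep],
            raw=self.raw[:, keep].tocsr(),
            normalized=None if self.normalized is None else self.normalized[:, keep],
            scale_factor=self.scale_factor,
        )


def check_aligned(cells: pd.DataFrame, counts: CountMatrix) -> None:
    """Raise :class:`AlignmentError` unless the table and matrix list the
    same cells in the same order."""
    ids = pd.Index(cells["cell_id"])
    if len(ids) != counts.n_cells or not ids.equals(counts.cells):
        extra = ids.difference(counts.cells).tolist()
        missing = counts.cells.difference(ids).tolist()
        raise AlignmentError(
            "cell table and count matrix misaligned: "
            f"{len(ids)} metadata rows vs {counts.n_cells} matrix columns; "
            f"metadata-only ids {extra[:5]}; matrix-only ids {missing[:5]}"
        )
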