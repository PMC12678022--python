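"""Reading, cell-level quality control, and normalization.

The QC rules are those used for segmented single-molecule spatial data:
cells with fewer than 20 total counts, or with an area more than 5 times
the average cell area, are removed; the area mean is computed once over
the pre-filter population (per sample by default) in a single pass.
Normalization divides each cell by its total count, rescales to a common
per-cell total, and square-root transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .containers import AlignmentError, CountMatrix, check_aligned, validate_cell_table


class FormatError(ValueError):
    """Malformed input file."""


class QcError(ValueError):
    """QC produced an unusable dataset (e.g. no cells survive)."""


@dataclass(frozen=True)
class QcParams:
    """Cell-filter thresholds.

    min_counts: minimum total transcript count per cell (cells *below* are
    removed). area_fold: multiple of the mean cell area above which a cell
    is removed. area_scope: "sample" computes the area mean within each
    sample; "global" over the whole table.
    """

    min_counts: int = 20
    area_fold: float = 5.0
    area_scope: str = "sample"

    def __post_init__(self) -> None:
        if self.min_counts < 0:
            raise ValueError("min_counts must be >= 0")
        if self.area_fold <= 0:
            raise ValueError("area_fold must be > 0")
        if self.area_scope not in ("sample", "global"):
            raise ValueError("area_scope must be 'sample' or 'global'")


@dataclass
class QcReport:
    n_input: int
    n_low_counts: int
    n_large_area: int
    n_retained: int
    area_thresholds: Dict[str, float]
    params: QcParams

    def to_frame(self) -> pd.DataFrame:
        rows = dict(
            n_input=self.n_input,
            n_low_counts=self.n_low_counts,
            n_large_area=self.n_large_area,
            n_retained=self.n_retained,
            min_counts=self.params.min_counts,
            area_fold=self.params.area_fold,
        )
        for sample, thr in self.area_thresholds.items():
            rows[f"area_threshold[{sample}]"] = thr
        return pd.DataFrame({"metric": list(rows), "value": list(rows.values())})


def read_dataset(
    count_path: str, gene_index: str, metadata: str
) -> Tuple[pd.DataFrame, CountMatrix]:
    """Read a (counts, genes, cell-metadata) fixture into aligned objects.

    ``count_path`` may be a MatrixMarket ``.mtx`` (genes × cells, column
    order = metadata row order) or, for small fixtures, a dense delimited
    table (``.csv``/``.tsv``) with gene rows and cell-id columns, in which
    case ``gene_index`` may be omitted as ``None``.
    """
    cells = pd.read_csv(metadata, sep="\t")
    validate_cell_table(cells)
    ids = pd.Index(cells["cell_id"].astype(str))

    if count_path.endswith((".csv", ".tsv")):
        sep = "," if count_path.endswith(".csv") else "\t"
        dense = pd.read_csv(count_path, sep=sep, index_col=0)
        dense.columns = dense.columns.astype(str)
        extra = ids.difference(dense.columns).tolist()
        missing = pd.Index(dense.columns).difference(ids).tolist()
        if extra or missing:
            raise AlignmentError(
                f"metadata/count cell-id mismatch: metadata-only {extra[:5]}, "
                f"counts-only {missing[:5]}"
            )
        dense = dense[ids]  # align column order to metadata
        genes = pd.Index(dense.index.astype(str))
        raw = sp.csr_matrix(dense.to_numpy())
    else:
        try:
            raw = sp.csr_matrix(mmread(count_path))
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {count_path}: {exc}") from exc
        with open(gene_index) as fh:
            genes = pd.Index([line.strip() for line in fh if line.strip()])
        if raw.shape[0] != len(genes):
            raise FormatError(
                f"gene index lists {len(genes)} genes but matrix has {raw.shape[0]} rows"
            )
        if raw.shape[1] != len(ids):
            surplus = ids[raw.shape[1]:].tolist() if len(ids) > raw.shape[1] else []
            raise AlignmentError(
                f"metadata lists {len(ids)} cells but matrix has {raw.shape[1]} columns"
                + (f"; surplus metadata ids {surplus[:5]}" if surplus else "")
            )
    counts = CountMatrix(genes=genes, cells=ids, raw=raw)
    check_aligned(cells, counts)
    return cells, counts


def qc_filter(
    cells: pd.DataFrame, counts: CountMatrix, params: QcParams = QcParams()
) -> Tuple[pd.DataFrame, CountMatrix, QcReport]:
    """Apply the two cell filters in a single pass.

    A cell is retained iff total counts >= ``min_counts`` AND area <=
    ``area_fold`` × mean(area), the mean taken over *all* input cells
    (pre-filter, not recomputed) within the configured scope.
    """
    check_aligned(cells, counts)
    n = len(cells)
    if n == 0:
        report = QcReport(0, 0, 0, 0, {}, params)
        return cells.copy(), counts.subset_cells(np.array([], int)), report

    totals = counts.cell_totals()
    low_counts = totals < params.min_counts

    areas = cells["area_um2"].to_numpy(float)
    thresholds: Dict[str, float] = {}
    large_area = np.zeros(n, dtype=bool)
    if params.area_scope == "global":
        thr = params.area_fold * areas.mean()
        thresholds["all"] = thr
        large_area = areas > thr
    else:
        for sample, idx in cells.groupby("sample_id").indices.items():
            thr = params.area_fold * areas[idx].mean()
            thresholds[str(sample)] = thr
            large_area[idx] = areas[idx] > thr

    keep = ~(low_counts | large_area)
    if not keep.any():
        raise QcError(
            f"empty after QC: all {n} cells removed "
            f"({int(low_counts.sum())} low-count, {int(large_area.sum())} large-area)"
        )
    report = QcReport(
        n_input=n,
        n_low_counts=int(low_counts.sum()),
        n_large_area=int(large_area.sum()),
        n_retained=int(keep.sum()),
        area_thresholds=thresholds,
        params=params,
    )
    return cells.loc[keep].reset_index(drop=True), counts.subset_cells(keep), report


def normalize_counts(
    counts: CountMatrix, scale_factor: Union[float, str] = "median"
) -> CountMatrix:
    """Total-count normalize and square-root transform.

    normalized[g, c] = sqrt(raw[g, c] / total(c) * s) with s the given
    scale factor or the median cell total when ``"median"``. The chosen s
    is recorded on the returned matrix. Zero-total cells are rejected.
    """
    totals = counts.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise QcError(f"cells with zero total counts: {counts.cells[zero].tolist()[:5]}")
    if isinstance(scale_factor, str):
        if scale_factor != "median":
            raise ValueError(f"unknown scale_factor {scale_factor!r}")
        s = float(np.median(totals))
    else:
        s = float(scale_factor)
        if s <= 0:
            raise ValueError("scale_factor must be positive")
    dense = np.asarray(counts.raw.todense(), dtype=float)
    normalized = np.sqrt(dense / totals[None, :] * s)
    return CountMatrix(
        genes=counts.genes,
        cells=counts.cells,
        raw=counts.raw,
        normalized=normalized,
        scale_factor=s,
    )
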