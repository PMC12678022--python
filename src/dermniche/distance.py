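"""Distance-to-cell-type maps and distance-conditioned expression analyses.

Supports the three readouts that localize expression programs along a
spatial axis: two-group differential expression between cells proximal
and distal to a target cell type (e.g. fibroblasts near vs far from
neutrophils), a genome-wide rank of expression–distance correlations, and
binned expression profiles against the epidermal boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata, spearmanr

from .containers import CountMatrix, validate_cell_table
from .markers import rank_markers


class LabelError(ValueError):
    pass


class BinningError(ValueError):
    pass


@dataclass
class DistanceMap:
    """Per-cell distance (μm) to the nearest cell of ``target_type``.

    Distances are computed within each sample; cells in samples with no
    target cells get NaN and are flagged ``undefined``.
    """

    distance: pd.Series  # index cell_id
    target_type: str

    @property
    def undefined(self) -> pd.Series:
        return self.distance.isna()


@dataclass(frozen=True)
class DistanceBins:
    """Proximal/distal distance thresholds (μm) for two-group DE."""

    proximal_max: float = 30.0
    distal_min: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.proximal_max < self.distal_min:
            raise ValueError("require 0 < proximal_max < distal_min")


#: Thresholds printed in the lesional figure legend (<30 μm vs >300 μm).
FIGURE_BINS = DistanceBins(30.0, 300.0)
#: Alternative thresholds used in the running text (<10 μm vs >50 μm).
TEXT_BINS = DistanceBins(10.0, 50.0)


def distance_to_nearest(cells: pd.DataFrame, target_type: str) -> DistanceMap:
    """Euclidean distance from every cell to its sample's nearest
    ``target_type`` cell (0 for target cells themselves)."""
    validate_cell_table(cells, require_type=True)
    if target_type not in set(cells["cell_type"]):
        raise LabelError(f"no cells of target type {target_type!r} in any sample")
    out = np.full(len(cells), np.nan)
    xy_all = cells[["x_um", "y_um"]].to_numpy(float)
    is_target = (cells["cell_type"] == target_type).to_numpy()
    for _, idx in cells.groupby("sample_id").indices.items():
        targets = idx[is_target[idx]]
        if targets.size == 0:
            continue  # stays NaN: flagged undefined
        tree = cKDTree(xy_all[targets])
        d, _ = tree.query(xy_all[idx], k=1)
        out[idx] = d
        out[targets] = 0.0
    return DistanceMap(
        distance=pd.Series(out, index=pd.Index(cells["cell_id"], name="cell_id"), name="distance_um"),
        target_type=target_type,
    )


def proximal_distal_de(
    counts: CountMatrix,
    cells: pd.DataFrame,
    dmap: DistanceMap,
    query_type: str,
    bins: DistanceBins = FIGURE_BINS,
    min_pct: float = 0.25,
    lfc_threshold: float = 0.2,
) -> pd.DataFrame:
    """Rank-sum DE between proximal and distal query-type cells.

    Group A: query cells with distance < ``bins.proximal_max``; group B:
    distance > ``bins.distal_min``; intermediate cells are excluded.
    Positive log2FC = higher in the proximal group.
    """
    merged = cells.set_index("cell_id").join(dmap.distance)
    query = merged[(merged["cell_type"] == query_type) & merged["distance_um"].notna()]
    prox = query.index[query["distance_um"] < bins.proximal_max].tolist()
    dist = query.index[query["distance_um"] > bins.distal_min].tolist()
    if len(prox) < 3 or len(dist) < 3:
        raise BinningError(
            f"need >= 3 {query_type} cells per bin; got proximal(<{bins.proximal_max}) = "
            f"{len(prox)}, distal(>{bins.distal_min}) = {len(dist)}"
        )
    return rank_markers(
        counts, prox, dist, min_pct=min_pct, lfc_threshold=lfc_threshold, group_label="proximal"
    )


def distance_correlation_rank(
    counts: CountMatrix,
    cells: pd.DataFrame,
    dmap: DistanceMap,
    query_type: str,
) -> pd.DataFrame:
    """Rank all genes by Spearman correlation of expression vs distance.

    Computed over query-type cells with defined distances; sorted
    ascending, so the most target-proximal-biased genes (most negative ρ)
    come first. Constant genes get ρ = 0 and are flagged.
    """
    merged = cells.set_index("cell_id").join(dmap.distance)
    query = merged[(merged["cell_type"] == query_type) & merged["distance_um"].notna()]
    if len(query) < 10:
        raise ValueError(f"need >= 10 {query_type} cells with defined distances, got {len(query)}")
    norm_layer = counts.require_normalized()
    cols = counts.cell_indexer(query.index.tolist())
    expr = norm_layer[:, cols]  # genes × query cells
    d = query["distance_um"].to_numpy(float)

    d_rank = rankdata(d)
    e_rank = rankdata(expr, axis=1)
    constant = expr.std(axis=1) == 0
    dc = d_rank - d_rank.mean()
    ec = e_rank - e_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((ec**2).sum(axis=1) * (dc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ec @ dc) / denom
    rho[constant | ~np.isfinite(rho)] = 0.0

    table = pd.DataFrame(
        {"gene": counts.genes, "spearman_rho": rho, "constant": constant, "n_cells": len(query)}
    ).sort_values(["spearman_rho", "gene"], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def boundary_profile(
    counts: CountMatrix,
    cells: pd.DataFrame,
    gene: str,
    n_bins: int = 20,
    epidermis_depth_um: float = 100.0,
) -> Tuple[pd.DataFrame, float, float]:
    """Mean expression of ``gene`` in equal-width bins of distance from the
    epidermal boundary (the line y = ``epidermis_depth_um``).

    Returns ``(profile, trend_rho, trend_p)`` where the trend is the
    Spearman correlation of per-cell expression with boundary distance.
    """
    expr = counts.gene_row(gene)  # KeyError for unknown gene
    merged = cells.set_index("cell_id")
    expr = pd.Series(expr, index=counts.cells).loc[merged.index].to_numpy()
    d = np.abs(merged["y_um"].to_numpy(float) - epidermis_depth_um)
    edges = np.linspace(0.0, d.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    profile = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "d_min": edges[:-1],
            "d_max": edges[1:],
            "mean_expression": [
                expr[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)
            ],
            "n_cells": [(which == b).sum() for b in range(n_bins)],
        }
    )
    if np.std(expr) == 0 or np.std(d) == 0:
        return profile, 0.0, 1.0
    rho, p = spearmanr(expr, d)
    return profile, float(rho), float(p)
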