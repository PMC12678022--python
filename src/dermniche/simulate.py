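"""Seeded synthetic skin-tissue generator.

Emulates the structure a segmented single-molecule spatial transcriptomics
export of inflamed skin presents to the analysis pipeline:

* a layered geometry — an epidermal band at the top of the image
  (y < ``epidermis_depth_um``) over a stack of dermal bands, each with its
  own cell-type composition (the planted "niches");
* in lesional ("SS") tissue, a neutrophil-rich band in the mid-to-upper
  dermis, the only place neutrophils occur, so that distance-to-neutrophil
  is a meaningful axis across the whole section;
* per-cell-type negative-binomial expression programs over a small gene
  panel (type markers + shared background genes);
* chemokine analogs in fibroblasts whose negative-binomial mean is coupled
  to an anchor distance — the nearest neutrophil or the epidermal
  boundary — multiplicatively, ``mean * exp(±effect_size * d / height)``.

Everything is deterministic given ``TissueConfig.seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.spatial import cKDTree

from .containers import CountMatrix, validate_cell_table

NEAREST_NEUTROPHIL = "nearest_neutrophil"
EPIDERMIS_BOUNDARY = "epidermis_boundary"


class ConfigurationError(ValueError):
    """Invalid tissue configuration."""


@dataclass(frozen=True)
class Region:
    """A horizontal tissue band with its own cell-type composition.

    ``composition`` maps cell-type name to its fraction within the band and
    must sum to 1. Bands are half-open ``[y_min, y_max)`` except the last,
    which is closed at the tissue bottom.
    """

    name: str
    y_min: float
    y_max: float
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise ConfigurationError(f"region {self.name}: empty y range")
        fracs = np.array(list(self.composition.values()), float)
        if (fracs < 0).any() or (fracs > 1).any() or abs(fracs.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                f"region {self.name}: composition must be fractions summing to 1"
            )


@dataclass(frozen=True)
class GradientGene:
    """A gene whose expression is coupled to an anchor distance.

    direction "decreasing" means expression falls with distance from the
    anchor (a neutrophil-proximal program); "increasing" the opposite.
    The coupling applies only to cells of ``cell_type`` (None = all cells).
    """

    gene: str
    anchor: str  # NEAREST_NEUTROPHIL or EPIDERMIS_BOUNDARY
    direction: str  # "increasing" | "decreasing"
    effect_size: float
    cell_type: Optional[str] = "fibroblast"

    def __post_init__(self) -> None:
        if self.anchor not in (NEAREST_NEUTROPHIL, EPIDERMIS_BOUNDARY):
            raise ConfigurationError(f"unknown anchor {self.anchor!r}")
        if self.direction not in ("increasing", "decreasing"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increasing" else -1


@dataclass(frozen=True)
class TissueConfig:
    """Full description of one synthetic tissue section."""

    width_um: float
    height_um: float
    epidermis_depth_um: float
    cell_types: Tuple[str, ...]
    regions: Tuple[Region, ...]
    gene_means: pd.DataFrame  # genes × cell_types negative-binomial means
    n_cells: int
    counts_dispersion: float = 3.0  # NB size parameter θ (smaller = noisier)
    gradient_genes: Tuple[GradientGene, ...] = ()
    area_mean_um2: float = 100.0
    area_cv: float = 0.5
    sample_id: str = "S1"
    condition: str = "SS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        if min(self.width_um, self.height_um, self.epidermis_depth_um) <= 0:
            raise ConfigurationError("tissue dimensions must be positive")
        if self.counts_dispersion <= 0:
            raise ConfigurationError("counts_dispersion must be positive")
        if len(self.gene_means.index) == 0:
            raise ConfigurationError("gene panel is empty")
        if self.gene_means.index.duplicated().any():
            raise ConfigurationError("duplicate genes in panel")
        missing_types = set(self.gene_means.columns) ^ set(self.cell_types)
        if missing_types:
            raise ConfigurationError(f"gene_means columns != cell_types: {missing_types}")
        for region in self.regions:
            unknown = set(region.composition) - set(self.cell_types)
            if unknown:
                raise ConfigurationError(f"region {region.name}: unknown types {unknown}")
        for gg in self.gradient_genes:
            if gg.gene not in self.gene_means.index:
                raise ConfigurationError(f"gradient gene {gg.gene!r} not in panel")
            if gg.cell_type is not None and gg.cell_type not in self.cell_types:
                raise ConfigurationError(f"gradient cell_type {gg.cell_type!r} unknown")
        self._check_tiling()

    def _check_tiling(self) -> None:
        # Regions must tile [0, height] without gaps or overlaps, otherwise
        # some cells would be unassignable (or doubly assigned).
        bands = sorted(self.regions, key=lambda r: r.y_min)
        cursor = 0.0
        for band in bands:
            if abs(band.y_min - cursor) > 1e-6:
                raise ConfigurationError(
                    f"regions overlap or leave a gap at y={cursor:g} (next: {band.name})"
                )
            cursor = band.y_max
        if abs(cursor - self.height_um) > 1e-6:
            raise ConfigurationError("regions do not cover the tissue down to height_um")


@dataclass
class SyntheticTissue:
    """A generated tissue: cell table + counts + ground truth."""

    cells: pd.DataFrame
    counts: CountMatrix
    truth: pd.DataFrame  # cell_id, true_type, true_region, d_neutrophil, d_epidermis
    gradient_truth: pd.DataFrame  # gene, anchor, direction, effect_size, cell_type
    config: TissueConfig


def _region_of(y: np.ndarray, regions: Sequence[Region], height: float) -> np.ndarray:
    edges = np.array([r.y_min for r in sorted(regions, key=lambda r: r.y_min)] + [height])
    order = sorted(range(len(regions)), key=lambda i: regions[i].y_min)
    band = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(regions) - 1)
    return np.array(order, int)[band]


def generate_tissue(config: TissueConfig) -> SyntheticTissue:
    """Generate a seeded synthetic tissue from ``config``.

    Cells are scattered uniformly over the tissue rectangle; each cell's
    type is drawn from the composition of the band containing it; counts
    are drawn per gene from negative binomials with type-specific means,
    modulated for gradient genes by ``exp(sign * effect * d / height)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    xy = rng.uniform((0, 0), (config.width_um, config.height_um), size=(n, 2))
    x, y = xy[:, 0], xy[:, 1]

    region_idx = _region_of(y, config.regions, config.height_um)
    type_names = list(config.cell_types)
    type_pos = {t: i for i, t in enumerate(type_names)}

    # per-region categorical draw of cell types
    types = np.empty(n, dtype=object)
    for ridx, region in enumerate(config.regions):
        mask = region_idx == ridx
        if not mask.any():
            continue
        probs = np.array([region.composition.get(t, 0.0) for t in type_names])
        types[mask] = rng.choice(type_names, size=mask.sum(), p=probs / probs.sum())

    # log-normal areas with the requested mean and coefficient of variation
    sigma2 = np.log(1.0 + config.area_cv**2)
    mu = np.log(config.area_mean_um2) - sigma2 / 2.0
    areas = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)

    # anchor distances
    d_epi = np.abs(y - config.epidermis_depth_um)
    neut_mask = types == "neutrophil"
    if neut_mask.any():
        tree = cKDTree(xy[neut_mask])
        d_neut, _ = tree.query(xy, k=1)
        d_neut[neut_mask] = 0.0
    else:
        d_neut = np.full(n, np.nan)

    # counts: genes × cells, NB(θ, mean) with gradient modulation
    theta = config.counts_dispersion
    type_codes = np.array([type_pos[t] for t in types])
    means = config.gene_means.to_numpy(float)[:, type_codes]  # genes × cells
    grad_by_gene: Dict[str, GradientGene] = {g.gene: g for g in config.gradient_genes}
    gene_loc = {g: i for i, g in enumerate(config.gene_means.index)}
    for gg in grad_by_gene.values():
        d = d_neut if gg.anchor == NEAREST_NEUTROPHIL else d_epi
        if np.isnan(d).all():
            continue  # no anchor cells in this tissue: gene stays at base level
        factor = np.exp(gg.sign * gg.effect_size * d / config.height_um)
        if gg.cell_type is not None:
            factor = np.where(types == gg.cell_type, factor, 1.0)
        means[gene_loc[gg.gene]] *= factor

    p = theta / (theta + np.maximum(means, 1e-300))
    counts = rng.negative_binomial(theta, p)
    counts[means <= 0] = 0

    cell_ids = [f"{config.sample_id}_c{i:05d}" for i in range(n)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x_um": x,
            "y_um": y,
            "area_um2": areas,
            "sample_id": config.sample_id,
            "condition": config.condition,
        }
    )
    validate_cell_table(cells)
    matrix = CountMatrix(
        genes=config.gene_means.index,
        cells=pd.Index(cell_ids),
        raw=sp.csr_matrix(counts),
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_type": types,
            "true_region": [config.regions[i].name for i in region_idx],
            "d_neutrophil": d_neut,
            "d_epidermis": d_epi,
        }
    )
    gradient_truth = pd.DataFrame(
        [
            {
                "gene": g.gene,
                "anchor": g.anchor,
                "direction": g.direction,
                "effect_size": g.effect_size,
                "cell_type": g.cell_type,
            }
            for g in config.gradient_genes
        ],
        columns=["gene", "anchor", "direction", "effect_size", "cell_type"],
    )
    return SyntheticTissue(cells, matrix, truth, gradient_truth, config)


def write_fixture(tissue: SyntheticTissue, directory: str) -> Dict[str, str]:
    """Write a tissue as the on-disk fixture set the readers consume.

    Emits ``counts.mtx`` (integer MatrixMarket, genes × cells),
    ``genes.txt`` (one gene per line), ``cells.tsv`` (cell metadata) and
    ``truth.tsv``. Returns the mapping of logical name → path.
    """
    if tissue.counts.n_genes == 0:
        raise ConfigurationError("tissue has an empty gene panel; nothing to write")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.mtx"),
        "genes": os.path.join(directory, "genes.txt"),
        "cells": os.path.join(directory, "cells.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    mmwrite(paths["counts"], sp.coo_matrix(tissue.counts.raw), field="integer")
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(tissue.counts.genes) + "\n")
    tissue.cells.to_csv(paths["cells"], sep="\t", index=False)
    tissue.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Default panels and templates
# ---------------------------------------------------------------------------

#: Marker genes used by the default panel, three per cell type.
DEFAULT_MARKERS: Dict[str, Tuple[str, str, str]] = {
    "keratinocyte": ("KRT14", "KRT5", "KRT10"),
    "fibroblast": ("COL1A1", "COL1A2", "DCN"),
    "neutrophil": ("FCGR3B", "CSF3R", "S100A8"),
    "t_cell": ("CD3E", "CD3D", "TRAC"),
    "macrophage": ("CD68", "CD163", "LYZ"),
    "endothelial": ("PECAM1", "VWF", "CDH5"),
    "mast": ("TPSAB1", "TPSB2", "CPA3"),
}

DEFAULT_TYPES: Tuple[str, ...] = tuple(DEFAULT_MARKERS)

#: Neutrophil-anchored chemokine analogs of the default lesional panel.
PROXIMAL_CHEMOKINE = "CXCL1"  # falls with distance from neutrophils
DISTAL_CHEMOKINE = "CXCL12"  # rises with distance from neutrophils


def default_gene_panel(
    cell_types: Sequence[str] = DEFAULT_TYPES,
    n_background: int = 60,
    marker_mean: float = 8.0,
    marker_background: float = 0.2,
    chemokine_mean: float = 6.0,
    chemokine_background: float = 0.1,
    panel_seed: int = 7_002_025,
) -> pd.DataFrame:
    """Genes × cell-types table of negative-binomial means.

    Three high-mean markers per type, two fibroblast chemokine analogs, and
    ``n_background`` shared background genes whose (seeded, type-independent)
    means are log-uniform in [0.05, 3] — null genes for type-I-error checks.
    """
    rng = np.random.default_rng(panel_seed)
    rows: Dict[str, Dict[str, float]] = {}
    for ctype in cell_types:
        for gene in DEFAULT_MARKERS.get(ctype, ()):
            rows[gene] = {t: (marker_mean if t == ctype else marker_background) for t in cell_types}
    for gene in (PROXIMAL_CHEMOKINE, DISTAL_CHEMOKINE):
        rows[gene] = {
            t: (chemokine_mean if t == "fibroblast" else chemokine_background)
            for t in cell_types
        }
    bg_means = np.exp(rng.uniform(np.log(0.05), np.log(3.0), size=n_background))
    for i, m in enumerate(bg_means):
        rows[f"BG{i + 1:03d}"] = {t: float(m) for t in cell_types}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cell_types))


def ss_lesion_regions(height_um: float = 2400.0, epidermis_depth_um: float = 120.0) -> Tuple[Region, ...]:
    """The default lesional template: epidermis + six dermal bands.

    Neutrophils are densely packed in a mid-to-upper dermal band and taper
    into the two flanking bands, mimicking the dermal infiltrate of a
    lesion; the dermal bands otherwise differ in their fibroblast /
    lymphoid / vascular / mast make-up, with adjacent compositions
    contrasted enough that the seven planted regions are recoverable from
    50-μm neighborhood compositions.
    """
    e = epidermis_depth_um
    step = (height_um - e) / 6.0
    comps = [
        ("epidermis",
         {"keratinocyte": 0.74, "fibroblast": 0.06, "t_cell": 0.10, "macrophage": 0.10}),
        ("papillary_dermis",
         {"keratinocyte": 0.16, "fibroblast": 0.26, "neutrophil": 0.20, "t_cell": 0.22,
          "macrophage": 0.10, "endothelial": 0.06}),
        ("neutrophilic_infiltrate",
         {"fibroblast": 0.30, "neutrophil": 0.44, "t_cell": 0.08, "macrophage": 0.16,
          "endothelial": 0.02}),
        ("upper_reticular_dermis",
         {"fibroblast": 0.56, "neutrophil": 0.12, "t_cell": 0.04, "macrophage": 0.14,
          "endothelial": 0.10, "mast": 0.04}),
        ("mast_rich_dermis",
         {"fibroblast": 0.30, "t_cell": 0.06, "macrophage": 0.06, "endothelial": 0.18,
          "mast": 0.40}),
        ("mid_reticular_dermis",
         {"fibroblast": 0.52, "t_cell": 0.03, "macrophage": 0.03, "endothelial": 0.38,
          "mast": 0.04}),
        ("deep_vascular_dermis",
         {"fibroblast": 0.22, "t_cell": 0.02, "macrophage": 0.12, "endothelial": 0.42,
          "mast": 0.22}),
    ]
    regions = []
    y0 = 0.0
    for name, comp in comps:
        y1 = e if name == "epidermis" else y0 + step
        regions.append(Region(name, y0, min(y1, height_um), comp))
        y0 = y1
    return tuple(regions)


def ss_lesion_config(
    n_cells: int = 5000,
    seed: int = 0,
    effect_size: float = 2.0,
    width_um: float = 435.0,
    height_um: float = 2400.0,
    epidermis_depth_um: float = 120.0,
    gradient_genes: Optional[Tuple[GradientGene, ...]] = None,
    **kwargs,
) -> TissueConfig:
    """Default SS-lesion configuration.

    Plants seven composition regions and two fibroblast chemokine analogs:
    CXCL1-like (high near neutrophils) and CXCL12-like (high far from
    them), each with log-linear effect ``effect_size`` over the tissue
    height.
    """
    if gradient_genes is None:
        gradient_genes = (
            GradientGene(PROXIMAL_CHEMOKINE, NEAREST_NEUTROPHIL, "decreasing", effect_size),
            GradientGene(DISTAL_CHEMOKINE, NEAREST_NEUTROPHIL, "increasing", effect_size),
        )
    return TissueConfig(
        width_um=width_um,
        height_um=height_um,
        epidermis_depth_um=epidermis_depth_um,
        cell_types=DEFAULT_TYPES,
        regions=ss_lesion_regions(height_um, epidermis_depth_um),
        gene_means=default_gene_panel(),
        n_cells=n_cells,
        gradient_genes=gradient_genes,
        condition="SS",
        seed=seed,
        **kwargs,
    )


def healthy_regions(height_um: float = 2400.0, epidermis_depth_um: float = 120.0) -> Tuple[Region, ...]:
    """Healthy-control template: no neutrophils, quiet dermis."""
    e = epidermis_depth_um
    return (
        Region("epidermis", 0.0, e, {"keratinocyte": 0.92, "t_cell": 0.05, "macrophage": 0.03}),
        Region(
            "papillary_dermis",
            e,
            (height_um + e) / 2.0,
            {"fibroblast": 0.60, "endothelial": 0.20, "t_cell": 0.10, "macrophage": 0.10},
        ),
        Region(
            "reticular_dermis",
            (height_um + e) / 2.0,
            height_um,
            {"fibroblast": 0.55, "endothelial": 0.25, "mast": 0.12, "macrophage": 0.08},
        ),
    )


def healthy_config(n_cells: int = 5000, seed: int = 0, **kwargs) -> TissueConfig:
    """Healthy-control configuration: same panel, no neutrophil band, no
    distance-coupled chemokine programs."""
    return TissueConfig(
        width_um=435.0,
        height_um=2400.0,
        epidermis_depth_um=120.0,
        cell_types=DEFAULT_TYPES,
        regions=healthy_regions(),
        gene_means=default_gene_panel(),
        n_cells=n_cells,
        gradient_genes=(),
        condition="HC",
        sample_id=kwargs.pop("sample_id", "H1"),
        seed=seed,
        **kwargs,
    )
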