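"""Gene-set module scoring with expression-matched controls.

The module score of a cell for a gene set is the mean normalized
expression of the set's genes minus the mean of a pooled control set:
genes are binned by their dataset-average expression into ``n_bins``
equal-size bins and, for each set gene, up to ``n_ctrl`` control genes are
drawn (seeded, without replacement) from that gene's bin. Controls are
drawn from the bin *excluding* the set genes themselves, so a set gene
sitting a constant δ above its bin-mates scores exactly δ; when the
exclusion empties the pool the whole bin is used, so a set equal to an
entire bin scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

DEFAULT_N_BINS = 25
DEFAULT_N_CTRL = 100


class GeneSetError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: Sequence[str]
    note: str = ""

    def intersect(self, index: pd.Index) -> Sequence[str]:
        hits = [g for g in self.genes if g in index]
        if not hits:
            raise GeneSetError(f"gene set {self.name!r} shares no genes with the matrix")
        return hits


def read_gene_sets(path: str) -> Dict[str, GeneSet]:
    """Read gene sets from a two-column TSV (set_name, gene)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    return {
        name: GeneSet(name=name, genes=tuple(group["gene"]), note=f"read from {path}")
        for name, group in table.groupby("set_name")
    }


def module_score(
    counts: CountMatrix,
    gene_set: GeneSet,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score for one gene set (binned-control scheme).

    Deterministic given ``seed``; order of genes within the set does not
    matter (control draws are keyed to sorted set genes).
    """
    norm_layer = counts.require_normalized()
    set_genes = sorted(set(gene_set.intersect(counts.genes)))
    n_bins = min(n_bins, counts.n_genes)

    avg = norm_layer.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bins = np.array_split(order, n_bins)  # equal-size bins of gene positions
    bin_of = np.empty(counts.n_genes, int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    set_pos = np.array([counts.genes.get_loc(g) for g in set_genes])
    set_mask = np.zeros(counts.n_genes, bool)
    set_mask[set_pos] = True

    rng = np.random.default_rng(seed)
    control_pool = []
    for pos in set_pos:  # sorted gene order: permutation-invariant draws
        members = bins[bin_of[pos]]
        candidates = members[~set_mask[members]]
        if candidates.size == 0:
            candidates = members  # set covers the bin: controls = the bin itself
        k = min(n_ctrl, candidates.size)
        control_pool.append(rng.choice(candidates, size=k, replace=False))
    controls = np.concatenate(control_pool)

    score = norm_layer[set_pos].mean(axis=0) - norm_layer[controls].mean(axis=0)
    return pd.Series(score, index=counts.cells, name=gene_set.name)


def score_table(
    counts: CountMatrix,
    gene_sets: Mapping[str, GeneSet],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells × gene-sets table of module scores (one seeded draw per set)."""
    cols = {
        name: module_score(counts, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i)
        for i, (name, gs) in enumerate(sorted(gene_sets.items()))
    }
    return pd.DataFrame(cols, index=counts.cells)


def marker_mean_score(
    counts: CountMatrix, marker_dict: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Cells × labels table of mean normalized marker expression.

    The computable core of marker-based deconvolution summaries: each
    label's score in a cell is the mean normalized expression of the
    label's marker genes. Labels with no matching genes are skipped with a
    warning.
    """
    import warnings

    if not marker_dict:
        raise GeneSetError("empty marker dictionary")
    norm_layer = counts.require_normalized()
    cols = {}
    for label in sorted(marker_dict):
        hits = [g for g in marker_dict[label] if g in counts.genes]
        if not hits:
            warnings.warn(f"label {label!r}: no marker genes in panel; skipped")
            continue
        rows = [counts.genes.get_loc(g) for g in hits]
        cols[label] = norm_layer[rows].mean(axis=0)
    if not cols:
        raise GeneSetError("no label had marker genes in the panel")
    return pd.DataFrame(cols, index=counts.cells)
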