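"""Two-group rank-sum marker statistics and cluster annotation.

``rank_markers`` reproduces the field-standard marker test: genes are
prefiltered by detection fraction (the ``min.pct`` rule: detected in at
least ``min_pct`` of either group), compared by a two-sided Wilcoxon
rank-sum on the normalized layer (exact enumeration for tiny groups,
normal approximation with tie correction otherwise), given a pseudocount
log2 fold change, and Benjamini–Hochberg adjusted over the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

#: Exact enumeration is used when both groups are at most this large.
EXACT_MAX_N = 8

#: Pseudocount on group means in the log2 fold change.
LOG2FC_PSEUDOCOUNT = 1.0


class GroupingError(ValueError):
    """Invalid group definition (overlapping or empty groups)."""


def exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Enumerates every assignment of the pooled values into groups of sizes
    |a| and |b| and counts assignments whose rank-sum deviates from its
    mean at least as much as observed. Handles ties exactly (ranks are
    midranks of the actual pooled values).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    mu = na * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    total = comb(len(pooled), na)
    hits = sum(
        1
        for idx in combinations(range(len(pooled)), na)
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
    )
    return hits / total


def _asymptotic_ranksum_p(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p per gene row."""
    na, nb = mat_a.shape[1], mat_b.shape[1]
    n = na + nb
    pooled = np.concatenate([mat_a, mat_b], axis=1)
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :na].sum(axis=1)
    mu = na * (n + 1) / 2.0
    # tie correction: subtract sum(t^3 - t) over tie groups per gene
    sorted_vals = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, counts = np.unique(sorted_vals[g], return_counts=True)
        tie_term[g] = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mu) / np.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    p[~np.isfinite(z)] = 1.0  # fully tied gene: no evidence
    return np.minimum(p, 1.0)


def rank_markers(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_pct: float = 0.25,
    lfc_threshold: float = 0.2,
    group_label: str = "A",
) -> pd.DataFrame:
    """Two-group marker table on the normalized layer.

    Returns a DataFrame with one row per *tested* gene (detection filter:
    normalized > 0 in >= ``min_pct`` of group A or of group B), columns
    ``gene, group, log2_fc, pct_in, pct_out, p_raw, p_adj, significant``.
    Positive ``log2_fc`` means higher in group A. Significance flags rows
    with ``p_adj < 0.05`` and ``|log2_fc| > lfc_threshold``.
    """
    ids_a = list(group_a)
    ids_b = list(group_b)
    if not ids_a or not ids_b:
        raise GroupingError("both groups must be nonempty")
    if set(ids_a) & set(ids_b):
        raise GroupingError(f"groups overlap: {sorted(set(ids_a) & set(ids_b))[:5]}")
    norm_layer = counts.require_normalized()
    idx_a = counts.cell_indexer(ids_a)
    idx_b = counts.cell_indexer(ids_b)
    mat_a = norm_layer[:, idx_a]
    mat_b = norm_layer[:, idx_b]

    pct_in = (mat_a > 0).mean(axis=1)
    pct_out = (mat_b > 0).mean(axis=1)
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "group", "log2_fc", "pct_in", "pct_out", "p_raw", "p_adj", "significant"]
        )

    sub_a = mat_a[tested]
    sub_b = mat_b[tested]
    mean_a = sub_a.mean(axis=1)
    mean_b = sub_b.mean(axis=1)
    eps = LOG2FC_PSEUDOCOUNT
    log2_fc = np.log2((mean_a + eps) / (mean_b + eps))

    if len(ids_a) <= EXACT_MAX_N and len(ids_b) <= EXACT_MAX_N:
        p_raw = np.array([exact_ranksum_p(sub_a[g], sub_b[g]) for g in range(sub_a.shape[0])])
    else:
        p_raw = _asymptotic_ranksum_p(sub_a, sub_b)

    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": counts.genes[tested],
            "group": group_label,
            "log2_fc": log2_fc,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    table["significant"] = (table["p_adj"] < 0.05) & (table["log2_fc"].abs() > lfc_threshold)
    return table.reset_index(drop=True)


def find_all_markers(
    counts: CountMatrix,
    labels: Mapping[str, str],
    min_pct: float = 0.25,
    lfc_threshold: float = 0.2,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker tables for every label, concatenated.

    ``labels`` maps cell_id -> group label. Groups with fewer than
    ``min_cells`` members are skipped.
    """
    by_group: Dict[str, list] = {}
    for cell, lab in labels.items():
        by_group.setdefault(str(lab), []).append(cell)
    tables = []
    for lab in sorted(by_group):
        ids_a = by_group[lab]
        if len(ids_a) < min_cells:
            continue
        ids_b = [c for l2, cs in by_group.items() if l2 != lab for c in cs]
        if len(ids_b) < min_cells:
            continue
        tables.append(
            rank_markers(counts, ids_a, ids_b, min_pct=min_pct, lfc_threshold=lfc_threshold, group_label=lab)
        )
    if not tables:
        return pd.DataFrame(
            columns=["gene", "group", "log2_fc", "pct_in", "pct_out", "p_raw", "p_adj", "significant"]
        )
    return pd.concat(tables, ignore_index=True)


@dataclass
class AnnotationMap:
    """Cluster -> cell-type label assignment with diagnostics.

    ``scores`` holds the mean marker-set expression of every label in every
    cluster; ``margin`` the gap between the winning and runner-up labels.
    """

    labels: Dict[int, str]
    scores: pd.DataFrame  # clusters × labels
    runner_up: Dict[int, Optional[str]]
    margin: Dict[int, float]
    ties: Sequence[int]

    def cell_labels(self, clusters: Mapping[str, int]) -> pd.Series:
        """Map per-cell cluster ids to cell-type labels."""
        return pd.Series(
            {cell: self.labels.get(cl, "unassigned") for cell, cl in clusters.items()},
            name="cell_type",
        )


def annotate_clusters(
    clusters: Mapping[str, int],
    counts: CountMatrix,
    marker_dict: Mapping[str, Sequence[str]],
) -> AnnotationMap:
    """Label clusters by their best-matching marker-gene set.

    For each cluster and candidate label, the score is the mean normalized
    expression of the label's marker genes averaged over the cluster's
    cells; the cluster takes the argmax label. All-zero scores give
    "unassigned"; exact ties are broken alphabetically and flagged.
    """
    if not marker_dict:
        raise ValueError("empty marker dictionary")
    norm_layer = counts.require_normalized()
    present: Dict[str, list] = {}
    for label, genes in marker_dict.items():
        hits = [g for g in genes if g in counts.genes]
        missing = sorted(set(genes) - set(hits))
        if missing:
            warnings.warn(f"label {label!r}: marker genes absent from panel: {missing}")
        if hits:
            present[label] = [counts.genes.get_loc(g) for g in hits]
    if not present:
        raise ValueError("no marker genes found in the gene index")

    cluster_ids = sorted(set(clusters.values()))
    cell_pos = counts.cell_indexer(list(clusters.keys()))
    cl_arr = np.array(list(clusters.values()))
    scores = pd.DataFrame(index=cluster_ids, columns=sorted(present), dtype=float)
    for cl in cluster_ids:
        cols = cell_pos[cl_arr == cl]
        for label, rows in present.items():
            scores.loc[cl, label] = norm_layer[np.ix_(rows, cols)].mean()

    labels: Dict[int, str] = {}
    runner_up: Dict[int, Optional[str]] = {}
    margin: Dict[int, float] = {}
    ties = []
    for cl in cluster_ids:
        row = scores.loc[cl].sort_values(ascending=False, kind="stable")
        # alphabetical tie-break: sort_values is stable on the alphabetical column order
        best, best_val = row.index[0], row.iloc[0]
        if best_val <= 0:
            labels[cl] = "unassigned"
            runner_up[cl], margin[cl] = None, 0.0
            continue
        labels[cl] = str(best)
        runner_up[cl] = str(row.index[1]) if len(row) > 1 else None
        margin[cl] = float(best_val - (row.iloc[1] if len(row) > 1 else 0.0))
        if len(row) > 1 and np.isclose(best_val, row.iloc[1]):
            ties.append(cl)
    return AnnotationMap(labels, scores, runner_up, margin, tuple(ties))
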