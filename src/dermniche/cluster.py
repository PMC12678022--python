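"""Dimensionality reduction and graph clustering.

Cells are clustered the way the imaging-platform analyses do it: PCA on
the gene-standardized normalized matrix, a shared-nearest-neighbor graph
(Jaccard weights over the k-nearest-neighbor sets) in PC space, and
Leiden community detection at a chosen resolution. Cluster labels are
renumbered by decreasing size so runs are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix


class ParameterError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Per-cell cluster ids plus the embedding and parameters that made them."""

    labels: pd.Series  # index cell_id, values small ints (0 = largest cluster)
    embedding: pd.DataFrame  # cells × PCs
    params: Dict[str, object]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def as_mapping(self) -> Mapping[str, int]:
        return self.labels.to_dict()


def reduce_pca(counts: CountMatrix, n_pcs: int = 50, seed: int = 0) -> pd.DataFrame:
    """Top principal components of the gene-standardized normalized layer.

    Each gene is centered and scaled to unit variance (zero-variance genes
    contribute nothing); returns a cells × ``n_pcs`` DataFrame. Components
    are sign-stabilized by scikit-learn's deterministic SVD convention.
    """
    norm_layer = counts.require_normalized()
    max_pcs = min(counts.n_genes, counts.n_cells) - 1
    if n_pcs > max_pcs:
        raise ParameterError(f"n_pcs={n_pcs} exceeds min(genes, cells) - 1 = {max_pcs}")
    X = norm_layer.T.copy()  # cells × genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    pca = PCA(n_components=n_pcs, svd_solver="full" if max(X.shape) < 3000 else "randomized",
              random_state=seed)
    coords = pca.fit_transform(X)
    return pd.DataFrame(
        coords, index=counts.cells, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def snn_graph(embedding: np.ndarray, n_neighbors: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Two cells are connected if either is among the other's k nearest
    neighbors (self included, Euclidean); the weight is the Jaccard overlap
    of their neighbor sets. Edges with zero overlap are dropped.
    """
    n = embedding.shape[0]
    if n_neighbors > n:
        raise ParameterError(f"n_neighbors={n_neighbors} exceeds number of cells {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(embedding)
    knn = nn.kneighbors_graph(embedding, mode="connectivity")  # includes self
    shared = (knn @ knn.T).tocoo()  # |N(i) ∩ N(j)|
    union = 2 * n_neighbors - shared.data
    jaccard = shared.data / union
    mask = (shared.row != shared.col) & (jaccard > 0)
    return sp.csr_matrix((jaccard[mask], (shared.row[mask], shared.col[mask])), shape=(n, n))


def cluster_cells(
    embedding: pd.DataFrame,
    resolution: float = 0.4,
    n_neighbors: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Leiden clustering of the SNN graph at the given resolution.

    Deterministic given the seed; labels renumbered by decreasing cluster
    size (0 = largest).
    """
    coords = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ParameterError("embedding contains non-finite values")
    if len(embedding) < n_neighbors:
        raise ParameterError(
            f"fewer cells ({len(embedding)}) than n_neighbors ({n_neighbors})"
        )
    adj = snn_graph(coords, n_neighbors=n_neighbors)
    adj = ((adj + adj.T) / 2.0).tocoo()  # symmetrize; keep each edge once
    upper = adj.row < adj.col
    graph = ig.Graph(
        n=adj.shape[0],
        edges=list(zip(adj.row[upper], adj.col[upper])),
        edge_attrs={"weight": adj.data[upper].tolist()},
    )
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.array(partition.membership)
    # renumber by decreasing size, ties by original id for determinism
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=embedding.index, name="cluster")
    return ClusterResult(
        labels=labels,
        embedding=embedding if isinstance(embedding, pd.DataFrame) else pd.DataFrame(coords),
        params={
            "resolution": resolution,
            "n_neighbors": n_neighbors,
            "seed": seed,
            "n_pcs": coords.shape[1],
        },
    )
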