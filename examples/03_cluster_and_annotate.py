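"""Cluster cells on expression and annotate clusters with marker genes.

PCA on the gene-standardized normalized matrix, a shared-nearest-neighbor
graph, Leiden communities at resolution 0.4, and marker-based labels;
with the synthetic generator's ground truth available, the agreement of
the recovered labels can be measured directly.
"""

import pandas as pd

import dermniche as dn

tissue = dn.generate_tissue(dn.ss_lesion_config(n_cells=3000, seed=2))
cells = tissue.cells
_, counts, _ = dn.qc_filter(cells.assign(cell_type="unknown"), tissue.counts)
counts = dn.normalize_counts(counts)

embedding = dn.reduce_pca(counts, n_pcs=30, seed=0)
clusters = dn.cluster_cells(embedding, resolution=0.4, n_neighbors=20, seed=0)
print(f"Leiden found {clusters.n_clusters} clusters "
      f"(sizes: {clusters.labels.value_counts().sort_index().tolist()})")

amap = dn.annotate_clusters(
    clusters.as_mapping(), counts,
    {t: list(g) for t, g in dn.simulate.DEFAULT_MARKERS.items()},
)
print("cluster labels:", amap.labels)

predicted = amap.cell_labels(clusters.as_mapping())
truth = pd.Series(
    tissue.truth.set_index("cell_id")["true_type"].loc[predicted.index]
)
print(f"agreement with generator truth: {(predicted == truth).mean():.1%}")

markers = dn.find_all_markers(counts, {c: str(l) for c, l in clusters.as_mapping().items()})
top = markers[markers["significant"]].sort_values("log2_fc", ascending=False)
print("\ntop marker per cluster:")
print(top.groupby("group").head(1)[["group", "gene", "log2_fc", "p_adj"]].to_string(index=False))
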