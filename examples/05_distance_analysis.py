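"""Distance-conditioned fibroblast analyses.

Three readouts localize chemokine programs along the neutrophil axis:
(1) rank-sum DE between neutrophil-proximal (<30 μm) and -distal
(>300 μm) fibroblasts, (2) the genome-wide rank of expression-vs-distance
Spearman correlations, and (3) the niche-to-niche contrast that counts
positionally distinct chemokine programs.
"""

import dermniche as dn
from dermniche.niche import fit_niches, neighborhood_composition

tissue = dn.generate_tissue(dn.ss_lesion_config(n_cells=5000, seed=1))
cells = tissue.cells.assign(cell_type=tissue.truth["true_type"].to_numpy())
cells, counts, _ = dn.qc_filter(cells, tissue.counts)
counts = dn.normalize_counts(counts)

dmap = dn.distance_to_nearest(cells, "neutrophil")
fib = cells.set_index("cell_id")["cell_type"] == "fibroblast"
print(f"fibroblast-to-neutrophil distance: median "
      f"{dmap.distance[fib].median():.0f} um, max {dmap.distance[fib].max():.0f} um")

de = dn.proximal_distal_de(counts, cells, dmap, "fibroblast", bins=dn.FIGURE_BINS)
hits = de[de["significant"]].sort_values("log2_fc", ascending=False)
print(f"\nproximal (<{dn.FIGURE_BINS.proximal_max:.0f} um) vs distal "
      f"(>{dn.FIGURE_BINS.distal_min:.0f} um) fibroblast DE: "
      f"{len(hits)} significant genes")
print(hits[["gene", "log2_fc", "p_adj"]].to_string(index=False))

ranking = dn.distance_correlation_rank(counts, cells, dmap, "fibroblast")
print("\nmost neutrophil-proximal-biased genes (lowest Spearman rho):")
print(ranking.head(3)[["rank", "gene", "spearman_rho"]].to_string(index=False))
print("most neutrophil-distal-biased genes:")
print(ranking.tail(3)[["rank", "gene", "spearman_rho"]].to_string(index=False))

profiles = neighborhood_composition(cells, radius=50.0)
_, assignment = fit_niches(profiles, G=7, seed=1, cells=cells, epidermis_depth_um=120.0)
programs = dn.chemokine_niche_programs(
    counts, cells, assignment, chemokines=("CXCL1", "CXCL12")
)
print(f"\npositionally distinct fibroblast chemokine programs: {len(programs)}")
for niche, genes in programs.items():
    print(f"  niche {niche}: {', '.join(genes)}")
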