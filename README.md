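# dermniche

Spatial niche analysis of single-molecule skin transcriptomics.

Inflammatory skin diseases such as the neutrophilic dermatoses reorganize
the dermis into spatial *niches* — contiguous regions with distinctive
local cell-type composition — and reposition fibroblast states along the
axis of the neutrophil infiltrate. `dermniche` implements the analysis
chain that resolves this organization from a segmented cell-by-gene
spatial export (CosMx-style: counts + centroids + areas):

* **QC & normalization** — remove cells with < 20 counts or area > 5× the
  mean cell area; total-count normalize and square-root transform.
* **Clustering & markers** — PCA, shared-nearest-neighbor Leiden
  clustering (50 PCs, resolution 0.4), Wilcoxon rank-sum marker detection
  with the min.pct = 0.25 prefilter and Benjamini–Hochberg adjustment,
  marker-based cluster annotation.
* **Niche inference** — for each cell, the cell-type composition within a
  50 μm radius; a full-covariance Gaussian mixture (EM, BIC model
  selection or fixed G = 7) over those composition vectors defines the
  niches, labeled from the epidermis downward.
* **Distance analyses** — distance to the nearest neutrophil,
  proximal (< 30 μm) vs distal (> 300 μm) fibroblast differential
  expression, genome-wide expression-vs-distance Spearman ranking, and
  epidermal-boundary expression profiles.
* **Signature scoring** — binned-control module scores and marker-mean
  summaries.
* **Synthetic tissue generator** — seeded layered-skin simulations
  (epidermal band + six dermal bands, a dense mid-to-upper-dermal
  neutrophil infiltrate, negative-binomial expression programs, and
  chemokine analogs coupled to neutrophil distance) so every stage is
  testable end to end with known ground truth.

Formally, for cell *i* with neighbors *N(i)* = {*j* ≠ *i* : ‖x_j − x_i‖ ≤ r,
same sample}, the composition vector is p_i(t) = |{j ∈ N(i) : type(j) = t}| / |N(i)|;
niches are the components of a mixture Σ_g π_g 𝒩(μ_g, Σ_g) fitted to
{p_i} by EM, with G chosen by BIC = −2·logL + k·log n. Marker tests are
two-sided Wilcoxon rank-sum on sqrt-normalized expression with
log2FC = log2((m_A + 1)/(m_B + 1)), significant at p_adj < 0.05 and
|log2FC| > 0.2.

## Worked example

```python
import dermniche as dn
from dermniche.niche import fit_niches, neighborhood_composition

# a lesional section: 5000 cells, 7 planted regions, 2 chemokine gradients
tissue = dn.generate_tissue(dn.ss_lesion_config(n_cells=5000, seed=1))
cells = tissue.cells.assign(cell_type=tissue.truth["true_type"].to_numpy())
cells, counts, report = dn.qc_filter(cells, tissue.counts)
counts = dn.normalize_counts(counts)

profiles = neighborhood_composition(cells, radius=50.0)
model, assignment = fit_niches(profiles, G="auto", g_range=range(1, 13),
                               seed=1, cells=cells, epidermis_depth_um=120.0)
print(model.selected_G)                  # 7  — the planted region count

dmap = dn.distance_to_nearest(cells, "neutrophil")
de = dn.proximal_distal_de(counts, cells, dmap, "fibroblast")
print(de[de.significant][["gene", "log2_fc", "p_adj"]])
#      gene   log2_fc         p_adj
# 3   CXCL1  0.283486  8.039967e-36   — higher in neutrophil-proximal FBs
# 4  CXCL12 -0.280873  8.889884e-39   — higher in neutrophil-distal FBs

programs = dn.chemokine_niche_programs(counts, cells, assignment,
                                       chemokines=("CXCL1", "CXCL12"))
print(programs)                          # {3: ['CXCL1'], 7: ['CXCL12']}
```

The three printed results are the package's headline readout on synthetic
lesional tissue: BIC recovers the seven planted composition regions from
50-μm neighborhoods; the CXCL1 analog is significantly enriched in
neutrophil-proximal fibroblasts and the CXCL12 analog in distal ones; and
the niche-to-niche contrast resolves exactly two positionally distinct
fibroblast chemokine programs — an upper-dermal, neutrophil-adjacent one
and a deep-dermal, neutrophil-distal one.

Each capability has a narrative script under `examples/` (simulation, QC,
clustering, niche analysis, distance analyses, signature scores). A thin
CLI covers the shell-shaped entry points:

```bash
dermniche simulate --n-cells 5000 --seed 1 --out fixture/
dermniche run-all --config pipeline.yaml --out run/
```

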