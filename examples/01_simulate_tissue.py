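"""Generate a synthetic lesional skin section and inspect its structure.

The default template stacks an epidermal band over six dermal bands with
distinct cell-type compositions; neutrophils are densely packed in the
mid-to-upper dermis, and two fibroblast chemokine analogs are coupled to
the distance from the nearest neutrophil (CXCL1-like falls with distance,
CXCL12-like rises).
"""

import dermniche as dn

config = dn.ss_lesion_config(n_cells=5000, seed=1)
tissue = dn.generate_tissue(config)

print(f"tissue: {config.width_um:.0f} x {config.height_um:.0f} um, "
      f"{config.n_cells} cells, {tissue.counts.n_genes} genes")
print(f"mean counts per cell: {tissue.counts.cell_totals().mean():.1f}")
print("\ncells per planted region:")
print(tissue.truth["true_region"].value_counts().to_string())
print("\ncell-type fractions:")
print(tissue.truth["true_type"].value_counts(normalize=True).round(3).to_string())
print("\ndistance-coupled genes:")
print(tissue.gradient_truth.to_string(index=False))

# The counts, metadata and ground truth can be written as a plain-text
# fixture set (MatrixMarket + TSV) and re-read by the qc module:
paths = dn.write_fixture(tissue, "scratch/example_fixture")
print("\nwrote:", ", ".join(paths.values()))
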