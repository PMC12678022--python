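"""Cell-level quality control and normalization.

Cells with fewer than 20 transcripts, or with a segmented area more than
5x the average cell area, are removed (the area mean is taken once over
the pre-filter population, per sample). Counts are then divided by the
per-cell total, rescaled to the median cell total, and square-root
transformed; the per-cell sum of squared normalized values equals the
scale factor exactly.
"""

import numpy as np

import dermniche as dn

tissue = dn.generate_tissue(dn.ss_lesion_config(n_cells=5000, seed=1))
cells = tissue.cells.assign(cell_type=tissue.truth["true_type"].to_numpy())

cells, counts, report = dn.qc_filter(cells, tissue.counts, dn.QcParams(min_counts=20, area_fold=5.0))
print(f"QC: kept {report.n_retained}/{report.n_input} cells "
      f"({report.n_low_counts} low-count, {report.n_large_area} large-area)")
print(f"area threshold(s): { {k: round(v, 1) for k, v in report.area_thresholds.items()} }")

counts = dn.normalize_counts(counts, scale_factor="median")
print(f"normalized to scale factor {counts.scale_factor:.1f} (median cell total)")

ss = (counts.normalized**2).sum(axis=0)
print(f"conservation check: per-cell sum of squared normalized values = "
      f"{ss.min():.6f}..{ss.max():.6f} (scale factor {counts.scale_factor:.1f})")
print(f"max relative deviation: {np.abs(ss / counts.scale_factor - 1).max():.2e}")
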