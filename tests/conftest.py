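import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import dermniche as dn
from dermniche.containers import CountMatrix


def make_counts(raw, genes=None, cells=None, normalized=None, scale_factor=None):
    """Build a CountMatrix from a dense array (genes × cells)."""
    raw = np.asarray(raw)
    genes = genes or [f"g{i}" for i in range(raw.shape[0])]
    cells = cells or [f"c{j}" for j in range(raw.shape[1])]
    return CountMatrix(
        genes=pd.Index(genes),
        cells=pd.Index(cells),
        raw=sp.csr_matrix(raw),
        normalized=normalized,
        scale_factor=scale_factor,
    )


def make_cells(xy, cell_type=None, sample_id="S1", condition="SS", area=100.0, ids=None):
    """Build a minimal valid cell table from coordinates."""
    xy = np.asarray(xy, float)
    n = len(xy)
    table = pd.DataFrame(
        {
            "cell_id": ids or [f"c{j}" for j in range(n)],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": np.full(n, area, float),
            "sample_id": sample_id if np.isscalar(sample_id) else sample_id,
            "condition": condition,
        }
    )
    if cell_type is not None:
        table["cell_type"] = cell_type
    return table


@pytest.fixture(scope="session")
def ss_tissue():
    """One default SS-lesion tissue, truth-annotated, QC'd and normalized."""
    tissue = dn.generate_tissue(dn.ss_lesion_config(seed=11))
    cells = tissue.cells.assign(cell_type=tissue.truth["true_type"].to_numpy())
    cells, counts, _ = dn.qc_filter(cells, tissue.counts)
    counts = dn.normalize_counts(counts)
    truth = tissue.truth.set_index("cell_id").loc[cells["cell_id"]].reset_index()
    return tissue.config, cells, counts, truth
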