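"""Distance maps, proximal/distal DE, correlation ranking, boundary profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import dermniche as dn
from dermniche.distance import (
    BinningError,
    DistanceBins,
    LabelError,
    boundary_profile,
    distance_correlation_rank,
    distance_to_nearest,
    proximal_distal_de,
)
from .conftest import make_cells, make_counts


class TestDistanceToNearest:
    def test_right_triangle(self):
        cells = make_cells([[0, 0], [3, 4]], cell_type=["neutrophil", "fibroblast"])
        dmap = distance_to_nearest(cells, "neutrophil")
        assert dmap.distance.loc["c1"] == pytest.approx(5.0)
        assert dmap.distance.loc["c0"] == 0.0

    def test_sample_without_targets_flagged(self):
        cells = make_cells(
            [[0, 0], [1, 1], [2, 2]], cell_type=["neutrophil", "fibroblast", "fibroblast"]
        )
        cells["sample_id"] = ["s1", "s1", "s2"]
        dmap = distance_to_nearest(cells, "neutrophil")
        assert dmap.undefined.loc["c2"]
        assert not dmap.undefined.loc["c1"]

    def test_unknown_target_rejected(self):
        cells = make_cells([[0, 0]], cell_type=["fibroblast"])
        with pytest.raises(LabelError):
            distance_to_nearest(cells, "martian")

    def test_equals_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        n = 500
        cells = make_cells(
            rng.uniform(0, 400, size=(n, 2)),
            cell_type=rng.choice(["neutrophil", "fibroblast", "t_cell"], size=n, p=[0.1, 0.6, 0.3]),
        )
        dmap = distance_to_nearest(cells, "neutrophil")
        xy = cells[["x_um", "y_um"]].to_numpy()
        targets = xy[(cells["cell_type"] == "neutrophil").to_numpy()]
        brute = np.sqrt(((xy[:, None, :] - targets[None]) ** 2).sum(-1)).min(1)
        brute[(cells["cell_type"] == "neutrophil").to_numpy()] = 0.0
        np.testing.assert_allclose(dmap.distance.to_numpy(), brute, atol=1e-9)


class TestProximalDistalDe:
    @staticmethod
    def _de_setup(ss_tissue):
        _, cells, counts, _ = ss_tissue
        dmap = distance_to_nearest(cells, "neutrophil")
        return cells, counts, dmap

    def test_planted_genes_recovered_with_correct_signs(self, ss_tissue):
        cells, counts, dmap = self._de_setup(ss_tissue)
        table = proximal_distal_de(counts, cells, dmap, "fibroblast")
        table = table.set_index("gene")
        prox = table.loc[dn.simulate.PROXIMAL_CHEMOKINE]
        dist = table.loc[dn.simulate.DISTAL_CHEMOKINE]
        assert prox["significant"] and prox["log2_fc"] > 0
        assert dist["significant"] and dist["log2_fc"] < 0

    def test_null_genes_not_significant(self, ss_tissue):
        """Background genes shared across regions give no discoveries."""
        cells, counts, dmap = self._de_setup(ss_tissue)
        table = proximal_distal_de(counts, cells, dmap, "fibroblast")
        null = table[table["gene"].str.startswith("BG")]
        assert (~null["significant"]).all()

    def test_swapped_bins_negate_log2fc(self, ss_tissue):
        cells, counts, dmap = self._de_setup(ss_tissue)
        merged = cells.set_index("cell_id").join(dmap.distance)
        fib = merged[merged["cell_type"] == "fibroblast"]
        prox = fib.index[fib["distance_um"] < 30].tolist()
        dist = fib.index[fib["distance_um"] > 300].tolist()
        t1 = dn.rank_markers(counts, prox, dist, min_pct=0.25)
        t2 = dn.rank_markers(counts, dist, prox, min_pct=0.25)
        np.testing.assert_allclose(t1["log2_fc"], -t2["log2_fc"], atol=1e-12)

    def test_alternative_text_thresholds_accepted(self, ss_tissue):
        cells, counts, dmap = self._de_setup(ss_tissue)
        table = proximal_distal_de(
            counts, cells, dmap, "fibroblast", bins=dn.TEXT_BINS
        )
        assert len(table) > 0

    def test_empty_bin_reports_occupancy(self, ss_tissue):
        cells, counts, dmap = self._de_setup(ss_tissue)
        with pytest.raises(BinningError, match="distal"):
            proximal_distal_de(
                counts, cells, dmap, "fibroblast", bins=DistanceBins(30.0, 1e6)
            )

    def test_bins_invariants(self):
        with pytest.raises(ValueError):
            DistanceBins(50.0, 30.0)


class TestDistanceCorrelationRank:
    def test_expression_equal_to_distance_ranks_last(self):
        rng = np.random.default_rng(1)
        n = 60
        xy = np.column_stack([np.zeros(n), np.linspace(0, 500, n)])
        types = np.array(["neutrophil"] + ["fibroblast"] * (n - 1))
        cells = make_cells(xy, cell_type=types)
        d = xy[:, 1]
        norm = np.vstack([d, rng.uniform(1, 2, size=n), 500 - d])
        counts = make_counts(np.zeros_like(norm), normalized=norm, scale_factor=1.0)
        dmap = distance_to_nearest(cells, "neutrophil")
        table = distance_correlation_rank(counts, cells, dmap, "fibroblast")
        assert table.iloc[-1]["gene"] == "g0" and table.iloc[-1]["spearman_rho"] == pytest.approx(1.0)
        assert table.iloc[0]["gene"] == "g2" and table.iloc[0]["spearman_rho"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_zero(self):
        n = 30
        xy = np.column_stack([np.zeros(n), np.linspace(0, 100, n)])
        cells = make_cells(xy, cell_type=["neutrophil"] + ["fibroblast"] * (n - 1))
        norm = np.vstack([np.full(n, 2.0), np.linspace(0, 1, n)])
        counts = make_counts(np.zeros_like(norm), normalized=norm, scale_factor=1.0)
        dmap = distance_to_nearest(cells, "neutrophil")
        table = distance_correlation_rank(counts, cells, dmap, "fibroblast").set_index("gene")
        assert table.loc["g0", "constant"]
        assert table.loc["g0", "spearman_rho"] == 0.0

    def test_matches_scipy_spearman(self, ss_tissue):
        _, cells, counts, _ = ss_tissue
        dmap = distance_to_nearest(cells, "neutrophil")
        table = distance_correlation_rank(counts, cells, dmap, "fibroblast").set_index("gene")
        merged = cells.set_index("cell_id").join(dmap.distance)
        fib_ids = merged.index[merged["cell_type"] == "fibroblast"]
        cols = counts.cell_indexer(fib_ids)
        d = merged.loc[fib_ids, "distance_um"].to_numpy()
        for gene in [dn.simulate.PROXIMAL_CHEMOKINE, "BG001", "COL1A1"]:
            ref = spearmanr(counts.normalized[counts.genes.get_loc(gene), cols], d).statistic
            assert table.loc[gene, "spearman_rho"] == pytest.approx(ref, abs=1e-9)

    def test_planted_gradient_genes_occupy_opposite_extremes(self, ss_tissue):
        _, cells, counts, _ = ss_tissue
        dmap = distance_to_nearest(cells, "neutrophil")
        table = distance_correlation_rank(counts, cells, dmap, "fibroblast")
        ranks = table.set_index("gene")["rank"]
        n = len(table)
        assert ranks[dn.simulate.PROXIMAL_CHEMOKINE] <= n // 10  # most negative decile
        assert ranks[dn.simulate.DISTAL_CHEMOKINE] > n - n // 10  # most positive decile


class TestBoundaryProfile:
    @staticmethod
    def _epidermis_gradient_tissue(direction, seed=0):
        """Single-population dermis with one boundary-coupled gene that is
        expressed tissue-wide, so the trend is not diluted by zeros."""
        import pandas as pd

        cfg = dn.TissueConfig(
            width_um=500.0,
            height_um=2000.0,
            epidermis_depth_um=100.0,
            cell_types=("fibroblast",),
            regions=(dn.Region("dermis", 0.0, 2000.0, {"fibroblast": 1.0}),),
            gene_means=pd.DataFrame(
                {"fibroblast": [6.0, 1.0, 8.0]}, index=["CXCL1", "BG001", "ACTB"]
            ),
            n_cells=2000,
            gradient_genes=(
                dn.GradientGene(
                    "CXCL1", "epidermis_boundary", direction, 2.0, cell_type=None
                ),
            ),
            seed=seed,
        )
        tissue = dn.generate_tissue(cfg)
        cells = tissue.cells.assign(cell_type=tissue.truth["true_type"].to_numpy())
        cells, counts, _ = dn.qc_filter(cells, tissue.counts, dn.QcParams(min_counts=1))
        counts = dn.normalize_counts(counts, "median")
        return cells, counts, tissue.config

    def test_uniform_gene_has_flat_profile(self, ss_tissue):
        config, cells, counts, _ = ss_tissue
        profile, rho, _ = boundary_profile(
            counts, cells, "BG001", n_bins=20, epidermis_depth_um=config.epidermis_depth_um
        )
        assert len(profile) == 20
        assert abs(rho) < 0.1

    def test_epidermis_decreasing_gene_negative_trend(self):
        cells, counts, cfg = self._epidermis_gradient_tissue("decreasing")
        _, rho, p = boundary_profile(
            counts, cells, "CXCL1", epidermis_depth_um=cfg.epidermis_depth_um
        )
        assert rho < 0 and p < 1e-4

    def test_epidermis_increasing_gene_positive_trend(self):
        cells, counts, cfg = self._epidermis_gradient_tissue("increasing")
        _, rho, p = boundary_profile(
            counts, cells, "CXCL1", epidermis_depth_um=cfg.epidermis_depth_um
        )
        assert rho > 0 and p < 1e-4

    def test_unknown_gene_rejected(self, ss_tissue):
        _, cells, counts, _ = ss_tissue
        with pytest.raises(KeyError):
            boundary_profile(counts, cells, "NOPE")
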