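"""Neighborhood composition and Gaussian-mixture niche inference."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import dermniche as dn
from dermniche.niche import (
    GaussianMixtureEM,
    fit_niches,
    neighborhood_composition,
    niche_summary,
)
from .conftest import make_cells


def bruteforce_composition(cells, radius):
    """O(n²) reference implementation of neighborhood composition."""
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    types = sorted(cells["cell_type"].unique())
    samples = cells["sample_id"].to_numpy()
    n = len(cells)
    counts = np.zeros((n, len(types)))
    for i in range(n):
        for j in range(n):
            if i == j or samples[i] != samples[j]:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                counts[i, types.index(cells["cell_type"].iloc[j])] += 1
    tot = counts.sum(1, keepdims=True)
    fr = np.divide(counts, tot, out=np.zeros_like(counts), where=tot > 0)
    return fr, counts.sum(1).astype(int), types


class TestNeighborhoodComposition:
    def test_hand_example_three_cells(self):
        """Cells at x = 0 (A), 30 (B), 100 (A), radius 50: the first cell
        sees only the B cell."""
        cells = make_cells([[0, 0], [30, 0], [100, 0]], cell_type=["A", "B", "A"])
        prof = neighborhood_composition(cells, radius=50.0)
        assert prof.neighbor_count.tolist() == [1, 1, 0]
        assert prof.fractions.loc["c0"].to_dict() == {"A": 0.0, "B": 1.0}
        assert not prof.has_neighbors.loc["c2"]  # isolated cell flagged

    def test_default_radius_is_50_um(self):
        import inspect

        sig = inspect.signature(neighborhood_composition)
        assert sig.parameters["radius"].default == 50.0

    def test_equals_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            n = 120
            cells = make_cells(
                rng.uniform(0, 300, size=(n, 2)),
                cell_type=rng.choice(list("ABC"), size=n),
            )
            cells["sample_id"] = rng.choice(["s1", "s2"], size=n)
            prof = neighborhood_composition(cells, radius=60.0)
            fr, nc, types = bruteforce_composition(cells, 60.0)
            assert list(prof.fractions.columns) == types
            np.testing.assert_allclose(prof.fractions.to_numpy(), fr, atol=1e-12)
            np.testing.assert_array_equal(prof.neighbor_count.to_numpy(), nc)

    def test_fractions_sum_to_one_where_neighbors_exist(self, ss_tissue):
        _, cells, _, _ = ss_tissue
        prof = neighborhood_composition(cells.iloc[:1500], radius=50.0)
        sums = prof.fractions.to_numpy().sum(1)
        ok = prof.has_neighbors.to_numpy()
        np.testing.assert_allclose(sums[ok], 1.0, atol=1e-9)
        np.testing.assert_allclose(sums[~ok], 0.0)

    def test_unannotated_cells_rejected(self):
        cells = make_cells([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="cell_type"):
            neighborhood_composition(cells)


class TestGaussianMixtureEM:
    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.5, size=(200, 3)), rng.normal(2, 0.3, size=(150, 3))]
        )
        for cov in ("full", "diag"):
            m = GaussianMixtureEM(3, covariance=cov, seed=0, reg_covar=1e-6).fit(X)
            assert np.all(np.diff(m.loglik_trace) >= -1e-9), cov

    def test_matches_sklearn_oracle(self):
        """Same model family, init and floor: identical log-likelihoods."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.4, size=(250, 4)), rng.normal([2, 0, 1, -1], 0.3, size=(200, 4))]
        )
        mine = GaussianMixtureEM(2, covariance="full", seed=3, reg_covar=1e-6, n_init=1).fit(X)
        ref = GaussianMixture(
            2, covariance_type="full", reg_covar=1e-6, random_state=3,
            init_params="k-means++", n_init=3, max_iter=500,
        ).fit(X)
        assert mine.total_loglik(X) == pytest.approx(ref.score(X) * len(X), rel=1e-6)
        assert mine.bic(X) == pytest.approx(ref.bic(X), rel=1e-6)


class TestFitNiches:
    def test_identical_profiles_select_one_component(self):
        frac = pd.DataFrame(
            np.tile([0.5, 0.5], (80, 1)),
            index=pd.Index([f"c{j}" for j in range(80)], name="cell_id"),
            columns=["A", "B"],
        )
        prof = dn.NeighborhoodProfile(
            fractions=frac,
            neighbor_count=pd.Series(10, index=frac.index),
            radius=50.0,
        )
        model, assignment = fit_niches(prof, G="auto", g_range=range(1, 5), seed=0)
        assert model.selected_G == 1
        assert (assignment.labels == 1).all()

    def test_two_planted_compositions_recovered(self):
        """Dirichlet(200·center) compositions around two distinct centers:
        auto selects G = 2 with perfect agreement."""
        rng = np.random.default_rng(5)
        c1, c2 = np.array([0.7, 0.2, 0.1]), np.array([0.1, 0.3, 0.6])
        X = np.vstack(
            [rng.dirichlet(200 * c1, size=500), rng.dirichlet(200 * c2, size=500)]
        )
        truth = np.repeat([0, 1], 500)
        frac = pd.DataFrame(
            X, index=pd.Index([f"c{j}" for j in range(1000)], name="cell_id"),
            columns=["A", "B", "C"],
        )
        prof = dn.NeighborhoodProfile(
            fractions=frac, neighbor_count=pd.Series(30, index=frac.index), radius=50.0
        )
        model, assignment = fit_niches(prof, G="auto", g_range=range(1, 7), seed=1)
        assert model.selected_G == 2
        assert adjusted_rand_score(truth, assignment.labels.to_numpy()) == 1.0

    def test_bic_table_selects_minimum(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.dirichlet([60, 10, 10], 300), rng.dirichlet([10, 60, 10], 300)])
        frac = pd.DataFrame(
            X, index=pd.Index([f"c{j}" for j in range(600)], name="cell_id"),
            columns=list("ABC"),
        )
        prof = dn.NeighborhoodProfile(
            fractions=frac, neighbor_count=pd.Series(20, index=frac.index), radius=50.0
        )
        model, _ = fit_niches(prof, G="auto", g_range=range(1, 6), seed=2)
        assert model.selected_G == model.bic_table.idxmin()

    def test_cells_without_neighbors_left_unassigned(self):
        rng = np.random.default_rng(8)
        n = 60
        frac = pd.DataFrame(
            rng.dirichlet([5, 5], size=n),
            index=pd.Index([f"c{j}" for j in range(n)], name="cell_id"),
            columns=["A", "B"],
        )
        nc = pd.Series(10, index=frac.index)
        nc.iloc[:4] = 0
        frac.iloc[:4] = 0.0
        prof = dn.NeighborhoodProfile(fractions=frac, neighbor_count=nc, radius=50.0)
        _, assignment = fit_niches(prof, G=1, seed=0)
        assert (assignment.labels.iloc[:4] == 0).all()
        assert (assignment.labels.iloc[4:] == 1).all()

    def test_labels_ordered_by_epidermis_distance(self):
        """With geometry provided, niche 1 is the closest to the epidermal
        boundary."""
        rng = np.random.default_rng(9)
        upper = rng.dirichlet([80, 10], size=150)
        lower = rng.dirichlet([10, 80], size=150)
        frac = pd.DataFrame(
            np.vstack([lower, upper]),  # deliberately shuffled order: deep first
            index=pd.Index([f"c{j}" for j in range(300)], name="cell_id"),
            columns=["A", "B"],
        )
        cells = make_cells(
            np.column_stack(
                [np.zeros(300), np.concatenate([np.full(150, 900.0), np.full(150, 150.0)])]
            ),
            cell_type=["A"] * 300,
        )
        prof = dn.NeighborhoodProfile(
            fractions=frac, neighbor_count=pd.Series(20, index=frac.index), radius=50.0
        )
        _, assignment = fit_niches(
            prof, G=2, seed=0, cells=cells, epidermis_depth_um=100.0
        )
        labels = assignment.labels.to_numpy()
        assert set(labels[150:]) == {1}  # shallow cells -> niche 1
        assert set(labels[:150]) == {2}


class TestNicheSummary:
    def test_single_niche_proportions_are_one(self):
        cells = make_cells(np.zeros((10, 2)), cell_type=["A"] * 10)
        assignment = dn.NicheAssignment(
            labels=pd.Series(1, index=pd.Index(cells["cell_id"], name="cell_id")),
            posterior=pd.Series(1.0, index=pd.Index(cells["cell_id"], name="cell_id")),
        )
        by_cond, by_type = niche_summary(assignment, cells)
        assert by_cond.loc["SS", 1] == 1.0
        assert by_type.loc[1, "A"] == 1.0

    def test_rows_sum_to_one(self, ss_tissue):
        _, cells, _, _ = ss_tissue
        sub = cells.iloc[:2000]
        prof = neighborhood_composition(sub, radius=50.0)
        _, assignment = fit_niches(prof, G=4, seed=0)
        by_cond, by_type = niche_summary(assignment, sub)
        np.testing.assert_allclose(by_cond.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(by_type.sum(axis=1), 1.0, atol=1e-9)
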