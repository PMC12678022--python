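"""Neighborhood composition and mixture-model niche inference.

The niche analysis clusters cells not by their own expression but by the
cell-type make-up of their spatial surroundings: for every cell, the
fractions of each annotated cell type among neighbors within a fixed
radius (50 μm by default, self excluded, closed ball, neighbors restricted
to the same sample) form a composition vector; a Gaussian mixture fitted
to those vectors by EM defines the niches, with the number of components
either fixed (7 for parity with lesional skin sections) or selected by
BIC. Niche labels are ordered by mean distance from the epidermal
boundary, so niche 1 is the uppermost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .containers import CountMatrix, validate_cell_table
from .markers import rank_markers

DEFAULT_RADIUS_UM = 50.0

#: Default covariance regularization (added to every covariance diagonal).
#: Composition fractions have a resolution floor of ~1/neighbor_count
#: (they are multiples of it, ~0.03 at typical densities), so variances
#: much below (0.045)^2 ≈ 2e-3 are not physically meaningful; flooring
#: there also prevents the mixture from spending components on spatially
#: autocorrelated clumps of near-identical profiles (neighboring cells
#: share most of their neighbors) or on the thin mixing zones along
#: region boundaries.
DEFAULT_REG_COVAR = 2e-3


class ConvergenceError(RuntimeError):
    pass


@dataclass
class NeighborhoodProfile:
    """Per-cell neighborhood cell-type composition.

    ``fractions`` is cells × types (rows sum to 1 where ``neighbor_count``
    > 0 and are all-zero, flagged, otherwise).
    """

    fractions: pd.DataFrame
    neighbor_count: pd.Series
    radius: float

    @property
    def has_neighbors(self) -> pd.Series:
        return self.neighbor_count > 0


def neighborhood_composition(
    cells: pd.DataFrame, radius: float = DEFAULT_RADIUS_UM
) -> NeighborhoodProfile:
    """Cell-type composition within ``radius`` μm of each cell.

    Neighbors are cells of the same sample whose centroid lies within the
    closed Euclidean ball of the given radius, the index cell excluded.
    Counts are converted to fractions; cells without neighbors keep an
    all-zero row and are excluded from downstream niche fitting.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    validate_cell_table(cells, require_type=True)
    types = sorted(cells["cell_type"].unique())
    tpos = {t: i for i, t in enumerate(types)}
    n = len(cells)
    counts = np.zeros((n, len(types)))
    type_codes = cells["cell_type"].map(tpos).to_numpy()
    xy_all = cells[["x_um", "y_um"]].to_numpy(float)
    for _, idx in cells.groupby("sample_id").indices.items():
        xy = xy_all[idx]
        pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
        if len(pairs):
            gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
            np.add.at(counts, (gi, type_codes[gj]), 1)
            np.add.at(counts, (gj, type_codes[gi]), 1)
    totals = counts.sum(axis=1)
    fractions = np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0)
    return NeighborhoodProfile(
        fractions=pd.DataFrame(fractions, index=pd.Index(cells["cell_id"], name="cell_id"), columns=types),
        neighbor_count=pd.Series(totals.astype(int), index=pd.Index(cells["cell_id"], name="cell_id"), name="neighbor_count"),
        radius=float(radius),
    )


# ---------------------------------------------------------------------------
# Gaussian mixture by EM
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureEM:
    """EM-fitted Gaussian mixture over composition vectors.

    ``covariance`` is "full" (ellipsoidal components, the family the
    classic model-based clustering tool fits by default — compositions
    carry strong cross-type correlations that diagonal components cannot
    represent) or "diag". Component means are seeded with k-means++; the
    best of ``n_init`` seeded restarts (by log-likelihood) is kept.
    ``reg_covar`` is added to every covariance diagonal. The per-iteration
    mean log-likelihood trajectory of the winning run is kept on the
    fitted object (``loglik_trace``); it is non-decreasing, a property the
    test-suite asserts.
    """

    n_components: int
    covariance: str = "full"
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-7
    reg_covar: float = DEFAULT_REG_COVAR
    n_init: int = 3
    weights: Optional[np.ndarray] = None
    means: Optional[np.ndarray] = None
    covariances: Optional[np.ndarray] = None  # G×d×d (full) or G×d (diag)
    loglik_trace: Optional[np.ndarray] = None

    def _log_prob(self, X: np.ndarray) -> np.ndarray:
        """n × G matrix of log(weight_g · N(x | μ_g, Σ_g))."""
        n, d = X.shape
        G = self.n_components
        out = np.empty((n, G))
        if self.covariance == "diag":
            var = self.covariances
            log_det = np.log(var).sum(axis=1)
            quad = (((X[:, None, :] - self.means[None, :, :]) ** 2) / var[None, :, :]).sum(axis=2)
            out = -0.5 * (d * np.log(2 * np.pi) + log_det)[None, :] - 0.5 * quad
        else:
            for g in range(G):
                chol = np.linalg.cholesky(self.covariances[g])
                diff = X - self.means[g]
                z = np.linalg.solve(chol, diff.T)
                quad = (z**2).sum(axis=0)
                log_det = 2.0 * np.log(np.diag(chol)).sum()
                out[:, g] = -0.5 * (d * np.log(2 * np.pi) + log_det + quad)
        return np.log(self.weights)[None, :] + out

    def _m_step(self, X: np.ndarray, resp: np.ndarray) -> None:
        n, d = X.shape
        nk = resp.sum(axis=0) + 1e-300
        self.weights = nk / n
        self.means = (resp.T @ X) / nk[:, None]
        if self.covariance == "diag":
            diff2 = (X[:, None, :] - self.means[None, :, :]) ** 2
            self.covariances = np.einsum("ng,ngd->gd", resp, diff2) / nk[:, None] + self.reg_covar
        else:
            covs = np.empty((self.n_components, d, d))
            for g in range(self.n_components):
                diff = X - self.means[g]
                covs[g] = (resp[:, g][:, None] * diff).T @ diff / nk[g]
                covs[g].flat[:: d + 1] += self.reg_covar
            self.covariances = covs

    def _fit_once(self, X: np.ndarray, seed: int):
        n, d = X.shape
        G = self.n_components
        centers, _ = kmeans_plusplus(X, n_clusters=G, random_state=int(seed) % (2**31))
        self.means = centers.astype(float)
        self.weights = np.full(G, 1.0 / G)
        if self.covariance == "diag":
            self.covariances = np.tile(X.var(axis=0) + self.reg_covar, (G, 1))
        else:
            base = np.cov(X.T) + self.reg_covar * np.eye(d)
            self.covariances = np.tile(base, (G, 1, 1))
        trace = []
        prev = -np.inf
        for _ in range(self.max_iter):
            log_joint = self._log_prob(X)
            log_norm = logsumexp(log_joint, axis=1)
            loglik = log_norm.mean()
            trace.append(loglik)
            resp = np.exp(log_joint - log_norm[:, None])
            self._m_step(X, resp)
            if loglik - prev < self.tol * max(1.0, abs(loglik)):
                break
            prev = loglik
        else:
            if trace[-1] - prev > 1e-3 * max(1.0, abs(trace[-1])):
                raise ConvergenceError(
                    f"EM did not converge in {self.max_iter} iterations "
                    f"(last improvement {trace[-1] - prev:.3g})"
                )
        return trace, (self.weights, self.means, self.covariances)

    def fit(self, X: np.ndarray) -> "GaussianMixtureEM":
        X = np.asarray(X, float)
        if len(X) < self.n_components:
            raise ValueError(f"cannot fit {self.n_components} components to {len(X)} points")
        best = None
        for run in range(max(1, self.n_init)):
            trace, params = self._fit_once(X, self.seed + 7919 * run)
            if best is None or trace[-1] > best[0][-1]:
                best = (trace, params)
        trace, (self.weights, self.means, self.covariances) = best
        self.loglik_trace = np.array(trace)
        return self

    def total_loglik(self, X: np.ndarray) -> float:
        return float(logsumexp(self._log_prob(np.asarray(X, float)), axis=1).sum())

    def n_parameters(self) -> int:
        G, d = self.means.shape
        cov_params = G * d if self.covariance == "diag" else G * d * (d + 1) // 2
        return (G - 1) + G * d + cov_params

    def bic(self, X: np.ndarray) -> float:
        """−2·loglik + k·log n (lower is better)."""
        return -2.0 * self.total_loglik(X) + self.n_parameters() * np.log(len(X))

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        log_joint = self._log_prob(np.asarray(X, float))
        return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])


@dataclass
class NicheModel:
    mixture: GaussianMixtureEM
    bic_table: pd.Series  # index G, values BIC (lower is better)
    selected_G: int
    seed: int
    component_order: np.ndarray  # component index -> niche label - 1
    type_names: Sequence[str]

    @property
    def means(self) -> pd.DataFrame:
        ordered = self.mixture.means[self.component_order]
        return pd.DataFrame(
            ordered, index=pd.RangeIndex(1, self.selected_G + 1, name="niche"), columns=self.type_names
        )


@dataclass
class NicheAssignment:
    """Per-cell niche labels (1..G; 0 marks unprofiled cells without
    neighbors) and the posterior responsibility of the assigned niche."""

    labels: pd.Series
    posterior: pd.Series

    def covered(self) -> pd.Series:
        return self.labels[self.labels > 0]


def fit_niches(
    profiles: NeighborhoodProfile,
    G: Union[int, str] = "auto",
    g_range: Iterable[int] = range(1, 13),
    seed: int = 0,
    cells: Optional[pd.DataFrame] = None,
    epidermis_depth_um: Optional[float] = None,
    covariance: str = "full",
    reg_covar: float = DEFAULT_REG_COVAR,
) -> Tuple[NicheModel, NicheAssignment]:
    """Fit the niche mixture and assign every profiled cell.

    When ``G == "auto"`` every component count in ``g_range`` is fitted and
    the minimum-BIC model kept; otherwise G is fixed. If ``cells`` and
    ``epidermis_depth_um`` are given, niche labels 1..G are ordered by
    increasing mean distance from the epidermal boundary (niche 1
    uppermost); otherwise by decreasing component weight. Cells without
    neighbors get label 0 ("unassigned").
    """
    usable = profiles.has_neighbors.to_numpy()
    X = profiles.fractions.to_numpy(float)[usable]
    if len(X) < 10:
        raise ValueError(f"too few profiled cells ({len(X)}) to fit niches")

    def _fit(g: int) -> GaussianMixtureEM:
        return GaussianMixtureEM(
            n_components=g, covariance=covariance, seed=seed + 101 * g, reg_covar=reg_covar
        ).fit(X)

    bic_table: Dict[int, float] = {}
    if G == "auto":
        candidates = [g for g in g_range if 1 <= g <= len(X) // 10]
        if not candidates:
            raise ValueError("g_range leaves no admissible component counts")
        best: Optional[GaussianMixtureEM] = None
        for g in candidates:
            model = _fit(g)
            bic_table[g] = model.bic(X)
            if best is None or bic_table[g] < bic_table[best.n_components]:
                best = model
        mixture = best
        selected = mixture.n_components
    else:
        selected = int(G)
        mixture = _fit(selected)
        bic_table[selected] = mixture.bic(X)

    resp = mixture.responsibilities(X)
    hard = resp.argmax(axis=1)

    # order components: by epidermis distance when geometry is available
    if cells is not None and epidermis_depth_um is not None:
        d_epi = np.abs(cells["y_um"].to_numpy(float) - epidermis_depth_um)[usable]
        keys = []
        for g in range(selected):
            members = hard == g
            keys.append(d_epi[members].mean() if members.any() else np.inf)
        order = np.argsort(keys, kind="stable")
    else:
        order = np.argsort(-mixture.weights, kind="stable")
    rank_of = np.empty(selected, int)
    rank_of[order] = np.arange(selected)

    labels = np.zeros(len(profiles.fractions), int)
    labels[usable] = rank_of[hard] + 1
    posterior = np.zeros(len(profiles.fractions))
    posterior[usable] = resp[np.arange(len(X)), hard]

    model = NicheModel(
        mixture=mixture,
        bic_table=pd.Series(bic_table, name="bic").sort_index(),
        selected_G=selected,
        seed=seed,
        component_order=order,
        type_names=list(profiles.fractions.columns),
    )
    assignment = NicheAssignment(
        labels=pd.Series(labels, index=profiles.fractions.index, name="niche"),
        posterior=pd.Series(posterior, index=profiles.fractions.index, name="posterior"),
    )
    return model, assignment


def niche_summary(
    assignment: NicheAssignment, cells: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables of the niche partition.

    Returns ``(niche_by_condition, type_by_niche)``: the proportion of each
    niche within each condition (rows = condition, row-normalized) and the
    cell-type composition of each niche (rows = niche, row-normalized).
    Unassigned cells (label 0) are excluded.
    """
    merged = cells.set_index("cell_id").join(assignment.labels.rename("niche"))
    merged = merged[merged["niche"] > 0]
    niche_by_condition = (
        pd.crosstab(merged["condition"], merged["niche"], normalize="index")
        .rename_axis(index="condition", columns="niche")
    )
    type_by_niche = (
        pd.crosstab(merged["niche"], merged["cell_type"], normalize="index")
        .rename_axis(index="niche", columns="cell_type")
    )
    return niche_by_condition, type_by_niche


def chemokine_niche_programs(
    counts: CountMatrix,
    cells: pd.DataFrame,
    assignment: NicheAssignment,
    chemokines: Sequence[str],
    query_type: str = "fibroblast",
    target_type: str = "neutrophil",
    min_pct: float = 0.25,
    lfc_threshold: float = 0.2,
    min_cells: int = 20,
) -> Dict[int, list]:
    """Positionally distinct chemokine programs among query-type cells.

    Mirrors the niche-to-niche contrast used on lesional tissue: among
    niches holding at least ``min_cells`` cells of ``query_type``, the
    target-proximal extreme (smallest median distance of its query cells
    to the nearest ``target_type`` cell) is tested against the
    target-distal extreme by the rank-sum marker test. A chemokine
    significantly upregulated toward the proximal niche (p_adj < 0.05,
    log2FC > ``lfc_threshold``) marks that niche's program; one
    upregulated toward the distal niche marks the distal program. Each
    chemokine can mark only one niche, so markers are exclusive by
    construction. Returns niche label -> list of chemokine markers; the
    number of keys is the number of positionally distinct chemokine
    programs (0, 1 or 2).
    """
    from .distance import distance_to_nearest  # local import: avoid cycle

    merged = cells.set_index("cell_id").join(assignment.labels.rename("niche"))
    dmap = distance_to_nearest(cells, target_type)
    merged = merged.join(dmap.distance)
    query = merged[
        (merged["cell_type"] == query_type)
        & (merged["niche"] > 0)
        & merged["distance_um"].notna()
    ]
    sizes = query.groupby("niche").size()
    eligible = sizes.index[sizes >= min_cells]
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 niches with >= {min_cells} {query_type} cells; sizes: {dict(sizes)}"
        )
    med = query[query["niche"].isin(eligible)].groupby("niche")["distance_um"].median()
    proximal_niche = int(med.idxmin())
    distal_niche = int(med.idxmax())
    ids_prox = query.index[query["niche"] == proximal_niche].tolist()
    ids_dist = query.index[query["niche"] == distal_niche].tolist()
    table = rank_markers(
        counts, ids_prox, ids_dist, min_pct=min_pct, lfc_threshold=lfc_threshold
    ).set_index("gene")
    programs: Dict[int, list] = {}
    for gene in chemokines:
        if gene not in table.index or not table.loc[gene, "significant"]:
            continue
        home = proximal_niche if table.loc[gene, "log2_fc"] > 0 else distal_niche
        programs.setdefault(home, []).append(gene)
    return {k: sorted(v) for k, v in sorted(programs.items())}
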