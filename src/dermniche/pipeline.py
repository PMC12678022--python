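"""End-to-end pipeline: simulate/read → QC → normalize → annotate →
niche → distance → (optional) scoring, driven by one nested config.

Every stage writes its tables into the run directory; a resolved copy of
the configuration and a run log make the run reproducible — identical
config + seed gives identical outputs. One global seed derives per-stage
seeds by fixed offsets so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .cluster import cluster_cells, reduce_pca
from .distance import DistanceBins, distance_correlation_rank, distance_to_nearest, proximal_distal_de
from .markers import annotate_clusters, find_all_markers
from .niche import chemokine_niche_programs, fit_niches, neighborhood_composition, niche_summary
from .qc import QcParams, normalize_counts, qc_filter, read_dataset
from .signature import GeneSet, score_table

# fixed per-stage seed offsets derived from the global seed
STAGE_SEED_OFFSETS = {"simulate": 0, "cluster": 1, "niche": 2, "score": 3}


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Nested configuration for :func:`run_pipeline`.

    ``simulate`` holds synthetic-tissue parameters (``template``:
    "ss_lesion" or "healthy", plus n_cells / effect_size overrides);
    alternatively ``input`` points at counts/genes/metadata files with a
    truth-free annotation path. ``annotate.mode`` is "truth" (use the
    generator's true types) or "cluster" (PCA + Leiden + marker
    annotation).
    """

    seed: int = 0
    simulate: Optional[dict] = None
    input: Optional[dict] = None
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    niche: dict = field(default_factory=dict)
    distance: dict = field(default_factory=dict)
    score: Optional[dict] = None

    _ALLOWED = {
        "seed", "simulate", "input", "qc", "normalize", "annotate", "niche",
        "distance", "score",
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys("root", raw, cls._ALLOWED)
        cfg = cls(**raw)
        if (cfg.simulate is None) == (cfg.input is None):
            raise ConfigError("exactly one of [simulate] or [input] must be given")
        _check_keys("simulate", cfg.simulate or {}, {"template", "n_cells", "effect_size", "sample_id"})
        _check_keys("input", cfg.input or {}, {"counts", "genes", "metadata", "truth"})
        _check_keys("qc", cfg.qc, {"min_counts", "area_fold", "area_scope"})
        _check_keys("normalize", cfg.normalize, {"scale_factor"})
        _check_keys("annotate", cfg.annotate, {"mode", "n_pcs", "resolution", "n_neighbors", "marker_dict"})
        _check_keys("niche", cfg.niche, {"radius", "G", "g_min", "g_max", "epidermis_depth_um"})
        _check_keys("distance", cfg.distance, {"target", "query", "proximal_max", "distal_min", "chemokines"})
        _check_keys("score", cfg.score or {}, {"sets", "n_bins", "n_ctrl"})
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        """Full config with every default made explicit."""
        out = {
            "seed": self.seed,
            "qc": {"min_counts": 20, "area_fold": 5.0, "area_scope": "sample", **self.qc},
            "normalize": {"scale_factor": "median", **self.normalize},
            "annotate": {"mode": "cluster", "n_pcs": 50, "resolution": 0.4, "n_neighbors": 20,
                         **{k: v for k, v in self.annotate.items() if k != "marker_dict"}},
            "niche": {"radius": 50.0, "G": "auto", "g_min": 1, "g_max": 12,
                      "epidermis_depth_um": 120.0, **self.niche},
            "distance": {"target": "neutrophil", "query": "fibroblast",
                         "proximal_max": 30.0, "distal_min": 300.0,
                         "chemokines": [sim.PROXIMAL_CHEMOKINE, sim.DISTAL_CHEMOKINE],
                         **self.distance},
        }
        if self.simulate is not None:
            out["simulate"] = {"template": "ss_lesion", "n_cells": 5000, "effect_size": 2.0,
                               **self.simulate}
        if self.input is not None:
            out["input"] = dict(self.input)
        if self.score is not None:
            out["score"] = {"n_bins": 25, "n_ctrl": 100, **self.score}
        return out


def run_pipeline(config: PipelineConfig, out_dir: str) -> Dict[str, object]:
    """Execute every configured stage, writing tables into ``out_dir``.

    Returns a dict of in-memory results (cells, counts, niche model and
    assignment, marker/distance tables). Raises
    :class:`PipelineStageError` naming the failing stage; outputs of
    completed stages are retained on disk.
    """
    os.makedirs(out_dir, exist_ok=True)
    resolved = config.resolved()
    with open(os.path.join(out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)

    log = logging.getLogger("dermniche.pipeline")
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: Dict[str, object] = {}
    seed = int(config.seed)

    def stage(name):
        def deco(fn):
            try:
                fn()
                log.info("stage %s done", name)
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                handler.close()
                log.removeHandler(handler)
                raise PipelineStageError(name, exc) from exc
        return deco

    truth = None

    @stage("simulate")
    def _simulate():
        nonlocal truth
        if config.simulate is not None:
            p = resolved["simulate"]
            maker = sim.ss_lesion_config if p["template"] == "ss_lesion" else sim.healthy_config
            kwargs = dict(n_cells=p["n_cells"], seed=seed + STAGE_SEED_OFFSETS["simulate"])
            if p["template"] == "ss_lesion":
                kwargs["effect_size"] = p["effect_size"]
            tissue = sim.generate_tissue(maker(**kwargs))
            sim.write_fixture(tissue, os.path.join(out_dir, "simulated"))
            results["cells"], results["counts"], truth = tissue.cells, tissue.counts, tissue.truth
        else:
            p = resolved["input"]
            cells, counts = read_dataset(p["counts"], p.get("genes"), p["metadata"])
            results["cells"], results["counts"] = cells, counts
            if p.get("truth"):
                truth = pd.read_csv(p["truth"], sep="\t")
        log.info("loaded %d cells x %d genes", len(results["cells"]), results["counts"].n_genes)

    @stage("qc")
    def _qc():
        params = QcParams(**resolved["qc"])
        cells, counts, report = qc_filter(results["cells"], results["counts"], params)
        results["cells"], results["counts"], results["qc_report"] = cells, counts, report
        report.to_frame().to_csv(os.path.join(out_dir, "qc_report.tsv"), sep="\t", index=False)
        log.info("QC retained %d / %d cells", report.n_retained, report.n_input)

    @stage("normalize")
    def _normalize():
        results["counts"] = normalize_counts(results["counts"], resolved["normalize"]["scale_factor"])
        log.info("normalized (scale factor %.1f)", results["counts"].scale_factor)

    @stage("annotate")
    def _annotate():
        cells = results["cells"]
        mode = resolved["annotate"]["mode"]
        if mode == "truth":
            if truth is None:
                raise ConfigError("annotate.mode = truth requires simulated input or a truth table")
            mapping = truth.set_index("cell_id")["true_type"]
            cells = cells.assign(cell_type=cells["cell_id"].map(mapping).to_numpy())
        elif mode == "cluster":
            p = resolved["annotate"]
            emb = reduce_pca(results["counts"], n_pcs=min(p["n_pcs"], results["counts"].n_genes - 1),
                             seed=seed + STAGE_SEED_OFFSETS["cluster"])
            clusters = cluster_cells(emb, resolution=p["resolution"], n_neighbors=p["n_neighbors"],
                                     seed=seed + STAGE_SEED_OFFSETS["cluster"])
            marker_dict = config.annotate.get("marker_dict") or {
                t: list(g) for t, g in sim.DEFAULT_MARKERS.items()
            }
            amap = annotate_clusters(clusters.as_mapping(), results["counts"], marker_dict)
            labels = amap.cell_labels(clusters.as_mapping())
            cells = cells.assign(cell_type=labels.loc[cells["cell_id"]].to_numpy())
            find_all_markers(results["counts"],
                             {c: str(l) for c, l in clusters.as_mapping().items()}
                             ).to_csv(os.path.join(out_dir, "cluster_markers.tsv"), sep="\t", index=False)
            clusters.labels.rename("cluster").to_frame().assign(
                cell_type=labels.loc[clusters.labels.index].to_numpy()
            ).to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t")
        else:
            raise ConfigError(f"unknown annotate.mode {mode!r}")
        results["cells"] = cells
        cells.to_csv(os.path.join(out_dir, "cells_annotated.tsv"), sep="\t", index=False)
        log.info("annotated %d cells (%s mode)", len(cells), mode)

    @stage("niche")
    def _niche():
        p = resolved["niche"]
        profiles = neighborhood_composition(results["cells"], radius=p["radius"])
        model, assignment = fit_niches(
            profiles,
            G=p["G"],
            g_range=range(int(p["g_min"]), int(p["g_max"]) + 1),
            seed=seed + STAGE_SEED_OFFSETS["niche"],
            cells=results["cells"],
            epidermis_depth_um=p["epidermis_depth_um"],
        )
        results["niche_model"], results["niche_assignment"] = model, assignment
        results["profiles"] = profiles
        assignment.labels.to_frame().join(assignment.posterior).to_csv(
            os.path.join(out_dir, "niche_assignment.tsv"), sep="\t")
        model.bic_table.to_csv(os.path.join(out_dir, "niche_bic.tsv"), sep="\t")
        by_cond, by_type = niche_summary(assignment, results["cells"])
        by_cond.to_csv(os.path.join(out_dir, "niche_by_condition.tsv"), sep="\t")
        by_type.to_csv(os.path.join(out_dir, "celltype_by_niche.tsv"), sep="\t")
        log.info("fitted %d niches (BIC table: %s)", model.selected_G, dict(model.bic_table))

    @stage("distance")
    def _distance():
        p = resolved["distance"]
        cells = results["cells"]
        if p["target"] not in set(cells["cell_type"]):
            log.info("no %s cells; distance stage skipped", p["target"])
            return
        dmap = distance_to_nearest(cells, p["target"])
        dmap.distance.to_frame().to_csv(os.path.join(out_dir, "distance_to_target.tsv"), sep="\t")
        bins = DistanceBins(p["proximal_max"], p["distal_min"])
        de = proximal_distal_de(results["counts"], cells, dmap, p["query"], bins=bins)
        de.to_csv(os.path.join(out_dir, "proximal_distal_de.tsv"), sep="\t", index=False)
        corr = distance_correlation_rank(results["counts"], cells, dmap, p["query"])
        corr.to_csv(os.path.join(out_dir, "distance_correlation_rank.tsv"), sep="\t", index=False)
        programs = chemokine_niche_programs(
            results["counts"], cells, results["niche_assignment"], chemokines=p["chemokines"],
            query_type=p["query"])
        with open(os.path.join(out_dir, "chemokine_programs.json"), "w") as fh:
            json.dump({str(k): v for k, v in programs.items()}, fh, indent=1)
        results["distance_map"], results["proximal_distal_de"] = dmap, de
        results["distance_rank"], results["chemokine_programs"] = corr, programs
        log.info("distance analyses done (%d programs)", len(programs))

    if config.score is not None:
        @stage("score")
        def _score():
            p = resolved["score"]
            sets = {name: GeneSet(name, tuple(genes)) for name, genes in p["sets"].items()}
            table = score_table(results["counts"], sets, n_bins=p["n_bins"], n_ctrl=p["n_ctrl"],
                                seed=seed + STAGE_SEED_OFFSETS["score"])
            table.to_csv(os.path.join(out_dir, "module_scores.tsv"), sep="\t")
            results["module_scores"] = table

    handler.close()
    log.removeHandler(handler)
    return results
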