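"""End-to-end orchestration: scene -> filters -> counting -> candidates -> stability.

:func:`run_pipeline` chains the full perception flow on either a given
semantic cloud or a synthetic scene spec, persisting every intermediate
(filtered clouds, labeled cloud, cluster report, candidate table, stability
table, resolved configuration) and logging per-stage point counts and
timings to stderr.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import (
    SemanticPointCloud, dsc_filter, radius_outlier_removal,
    statistical_outlier_removal, write_ply,
)
from .clustering import BudCluster, count_buds
from .config import PipelineConfig
from .errors import TeaBudError
from .picking import (
    CandidatePoint, OFFSET_DKS, baseline_candidates, candidate_point,
    offset_candidate,
)
from .stability import evaluate_methods
from .synthetic import SceneSpec, SceneTruth, generate_tree

__all__ = ["PipelineResult", "run_pipeline", "candidates_table"]

log = logging.getLogger("teabud3d")


@dataclass
class PipelineResult:
    count: int
    clusters: list[BudCluster]
    bud_cloud: SemanticPointCloud
    candidates: pd.DataFrame
    stability: pd.DataFrame
    config: PipelineConfig
    truth: SceneTruth | None = None


def _stage(name: str, fn, cloud_in=None):
    t0 = time.perf_counter()
    try:
        out = fn()
    except TeaBudError:
        log.error("stage %s failed", name)
        raise
    dt = time.perf_counter() - t0
    n_in = len(cloud_in) if cloud_in is not None else "-"
    n_out = len(out) if hasattr(out, "__len__") and not isinstance(out, tuple) else "-"
    log.info("stage %-12s in=%s out=%s elapsed=%.3fs", name, n_in, n_out, dt)
    return out


def candidates_table(clusters: list[BudCluster], cloud: SemanticPointCloud,
                     cfg: PipelineConfig,
                     offsets: tuple[float, ...] = OFFSET_DKS) -> pd.DataFrame:
    """Candidate points for every cluster and method, as a flat table."""
    rows = []

    def add(cp: CandidatePoint, degenerate: bool) -> None:
        nx, ny, nz = (cp.plane_normal if cp.plane_normal is not None
                      else (np.nan, np.nan, np.nan))
        rows.append({"cluster_id": cp.cluster_id, "method": cp.method,
                     "dk": cp.dk, "x": cp.position[0], "y": cp.position[1],
                     "z": cp.position[2], "nx": nx, "ny": ny, "nz": nz,
                     "degenerate": degenerate})

    for ci, cluster in enumerate(clusters):
        pts = cloud.positions[cluster.point_indices]
        ours = candidate_point(pts, cfg.picking, ci)
        degenerate = ours.plane_normal is None
        add(ours, degenerate)
        for dk in offsets:
            if degenerate:
                add(CandidatePoint(position=ours.position, method="ours_offset",
                                   dk=dk, cluster_id=ci), True)
            else:
                add(offset_candidate(ours, dk, base_unit=cfg.picking.ransac_dist), False)
        for cand in baseline_candidates(pts, cfg.picking, ci):
            add(cand, False)
    return pd.DataFrame(rows)


def run_pipeline(source: SemanticPointCloud | SceneSpec,
                 cfg: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full perception pipeline and persist all artifacts.

    ``source`` is either an existing semantic cloud or a scene spec to
    generate first (in which case the ground truth is saved alongside).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if isinstance(source, SceneSpec):
        cloud, truth = _stage("simulate", lambda: generate_tree(source))
        truth.to_json(out / "truth.json")
    else:
        cloud = source
    write_ply(cloud, out / "scene.ply")

    f = cfg.filtering
    tree_cloud, bud_cloud = _stage(
        "dsc_filter", lambda: dsc_filter(cloud, f.sigma_min, f.prob_min), cloud)
    log.info("dsc split: tree=%d bud=%d", len(tree_cloud), len(bud_cloud))
    for stage in f.order:
        if stage == "sor" and len(bud_cloud) > f.sor_k:
            bud_cloud = _stage("sor", lambda: statistical_outlier_removal(
                bud_cloud, f.sor_k, f.sor_std_ratio), bud_cloud)
        elif stage == "ror":
            bud_cloud = _stage("ror", lambda: radius_outlier_removal(
                bud_cloud, f.ror_radius, f.ror_min_neighbors), bud_cloud)
    write_ply(bud_cloud, out / "buds.ply")

    count, clusters = _stage("count_buds",
                             lambda: count_buds(bud_cloud, cfg.clustering), bud_cloud)
    log.info("bud count: %d", count)

    labeled = bud_cloud.select(np.arange(len(bud_cloud)))
    labels = np.full(len(bud_cloud), -1, dtype=np.int32)
    for ci, cluster in enumerate(clusters):
        labels[cluster.point_indices] = ci
    labeled.label = labels
    write_ply(labeled, out / "labeled.ply")

    with open(out / "clusters.json", "w") as fh:
        json.dump({"count": count, "clusters": [
            {"id": ci, "n_points": int(len(c.point_indices)),
             "centroid": [float(v) for v in c.centroid],
             "volume": float(c.volume)}
            for ci, c in enumerate(clusters)]}, fh, indent=1)

    candidates = _stage("candidates",
                        lambda: candidates_table(clusters, bud_cloud, cfg))
    candidates.to_csv(out / "candidates.csv", index=False, float_format="%.9g")

    stability = _stage("stability", lambda: evaluate_methods(
        clusters, bud_cloud, cfg.stability, cfg.picking))
    stability.to_csv(out / "stability.csv", index=False, float_format="%.9g")

    cfg.to_yaml(out / "config_resolved.yaml")
    return PipelineResult(count=count, clusters=clusters, bud_cloud=bud_cloud,
                          candidates=candidates, stability=stability,
                          config=cfg, truth=truth)
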