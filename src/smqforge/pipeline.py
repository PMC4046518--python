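"""End-to-end pipeline: distance -> structuring -> clustering -> merging -> evaluation.

Driven by a single YAML config; every stage's artifacts are written to the
output directory together with a provenance stamp (config hash + seed).
The summary table reports macro precision / recall / F-measure per method
(semantic distance, terminology structuring, merging), one row each.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from smqforge import io as sfio
from smqforge.clustering import (
    ClusterConfig,
    graph_clusters,
    hac_clusters,
    merge_across,
    merge_within,
    radius_clusters,
)
from smqforge.distance import DistanceConfig, Measure, build_distance_matrix
from smqforge.evaluation import assign_and_report, baseline_hlt, cross_validate, percent
from smqforge.structuring import structure_terminology

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_THRESHOLDS = {Measure.RADA: 4.0, Measure.LCH: 4.10, Measure.ZHONG: 0.02}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report stage context
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - start)
            return result
        return inner
    return wrap


def load_config(config_path: str | Path) -> dict[str, Any]:
    with open(config_path, encoding="utf-8") as handle:
        return yaml.safe_load(handle)


def run_pipeline(config: str | Path | Mapping[str, Any]) -> Path:
    """Run the four-step workflow described by ``config``; returns out_dir."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out_dir = Path(config.get("out_dir", "smqforge-out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    term_cfg = config["terminology"]
    terminology = _stage("load")(sfio.read_terminology)(
        term_cfg["terms"], term_cfg["edges"], term_cfg.get("definitions")
    )
    lexicons = [
        _stage("load")(sfio.read_lexicon)(path) for path in config.get("lexicons", [])
    ]
    groupings = (
        _stage("load")(sfio.read_groupings)(config["groupings"])
        if config.get("groupings") else []
    )

    dist_cfg_raw = dict(config.get("distance", {}))
    measure = Measure(dist_cfg_raw.pop("measure", "rada"))
    dist_config = DistanceConfig(
        measure=measure,
        axis_weights=dict(dist_cfg_raw.get("weights", {"ADR": 1.0, "D": 2.0, "B": 1.0})),
        use_formal_definitions=bool(dist_cfg_raw.get("use_formal_definitions", True)),
        log_base=float(dist_cfg_raw.get("log_base", 2.0)),
        zhong_k=float(dist_cfg_raw.get("zhong_k", 2.0)),
    )
    matrix = _stage("distance")(build_distance_matrix)(terminology, None, dist_config)
    sfio.write_matrix(matrix, out_dir / "matrix.tsv")

    clu_cfg_raw = dict(config.get("clustering", {}))
    threshold = clu_cfg_raw.get("radius_threshold")
    if threshold is None:
        threshold = DEFAULT_RADIUS_THRESHOLDS[measure]
    cluster_config = ClusterConfig(
        radius_threshold=float(threshold),
        hac_k=int(clu_cfg_raw.get("hac_k", 300)),
        hac_linkage=clu_cfg_raw.get("hac_linkage", "average"),
        min_cluster_size=int(clu_cfg_raw.get("min_cluster_size", 2)),
        merge_overlap=float(clu_cfg_raw.get("merge_overlap", 0.8)),
    )

    cv_cfg = config.get("cross_validation")
    if cv_cfg and groupings:
        chosen = _stage("cross-validate")(cross_validate)(
            matrix, groupings, [float(t) for t in cv_cfg["grid"]],
            n_folds=int(cv_cfg.get("n_folds", 10)), seed=seed,
            cluster_config=cluster_config,
        )
        logger.info("cross-validated radius threshold: %s", chosen)
        cluster_config.radius_threshold = chosen

    method = clu_cfg_raw.get("method", "radius")
    if method == "hac":
        sd_clusters = _stage("cluster-sd")(hac_clusters)(matrix, cluster_config)
    else:
        sd_clusters = _stage("cluster-sd")(radius_clusters)(matrix, cluster_config)
    sd_clusters = _stage("merge-within")(merge_within)(sd_clusters, cluster_config)
    sfio.write_clusters(sd_clusters, out_dir / "clusters.sd.json")

    relations = _stage("structure")(structure_terminology)(terminology, lexicons)
    sfio.write_relations(relations, out_dir / "relations.tsv")
    struct_clusters = _stage("cluster-structuring")(graph_clusters)(relations)
    struct_clusters = _stage("merge-within")(merge_within)(struct_clusters, cluster_config)
    sfio.write_clusters(struct_clusters, out_dir / "clusters.structuring.json")

    merged = (
        _stage("merge-across")(merge_across)(sd_clusters, struct_clusters, cluster_config)
        if struct_clusters else list(sd_clusters)
    )
    sfio.write_clusters(merged, out_dir / "clusters.merged.json")

    summary_rows = []
    if groupings:
        branches = [
            ("semantic distance", sd_clusters),
            ("terminology structuring", struct_clusters),
            ("merging", merged),
        ]
        if config.get("baseline_hlt", False):
            branches.insert(0, ("baseline (HLT)", _stage("baseline")(baseline_hlt)(terminology)))
        for name, clusters in branches:
            if not clusters:
                summary_rows.append((name, 0, 0, 0))
                continue
            report = _stage("evaluate")(assign_and_report)(clusters, groupings)
            slug = name.split(" ")[0].split("(")[0] or "report"
            sfio.write_report(
                report, out_dir / f"report.{slug}.tsv", out_dir / f"report.{slug}.json"
            )
            summary_rows.append(
                (name, percent(report.macro_precision), percent(report.macro_recall),
                 percent(report.macro_f))
            )
        pd.DataFrame(
            summary_rows, columns=["method", "precision", "recall", "f_measure"]
        ).to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    stamp = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.items() if k != "out_dir"},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        "radius_threshold": cluster_config.radius_threshold,
        "measure": measure.value,
        "n_terms": len(matrix.term_ids),
        "n_sd_clusters": len(sd_clusters),
        "n_structuring_clusters": len(struct_clusters),
        "n_merged_clusters": len(merged),
    }
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as handle:
        json.dump(stamp, handle, indent=1, sort_keys=True)
    return out_dir
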