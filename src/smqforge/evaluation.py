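"""Evaluation of generated clusters against reference groupings.

Each generated cluster is associated with the reference grouping (SMQ-like
safety topic) maximising their F-measure; each grouping is then scored by
the best cluster assigned to it:

* precision — common terms / cluster size,
* recall — common terms / grouping size,
* F-measure — harmonic mean of the two (0 when both are 0).

Macro averages are unweighted means over all groupings.  A grouping to
which no cluster was assigned falls back to the globally best-F cluster and
is flagged, so both readings of the assignment protocol can be reproduced.
Threshold selection uses ten-fold cross-validation over the groupings: in
each fold one subset tunes the threshold (the grid value with the best
macro-F on it) and the modal winner across folds is retained.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from smqforge.clustering import Cluster, ClusterConfig, ClusterMethod, radius_clusters
from smqforge.model import Level, ReferenceGrouping, Terminology, ValidationError


def prf(cluster_members: Iterable[str], grouping_members: Iterable[str]) -> tuple[float, float, float]:
    """Precision, recall and F-measure of a cluster against a grouping."""
    cluster = frozenset(cluster_members)
    grouping = frozenset(grouping_members)
    if not cluster or not grouping:
        raise ValidationError("cluster and grouping must be non-empty")
    common = len(cluster & grouping)
    precision = common / len(cluster)
    recall = common / len(grouping)
    f = 0.0 if common == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def percent(fraction: float) -> int:
    """Integer percentage, rounding half away from zero."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass(frozen=True)
class EvaluationRecord:
    group_id: str
    best_cluster_id: str
    n_group: int
    n_cluster: int
    n_common: int
    precision: float
    recall: float
    f_measure: float
    fallback: bool = False


@dataclass
class EvaluationReport:
    records: list[EvaluationRecord]
    macro_precision: float = field(init=False)
    macro_recall: float = field(init=False)
    macro_f: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.records)
        self.macro_precision = sum(r.precision for r in self.records) / n if n else 0.0
        self.macro_recall = sum(r.recall for r in self.records) / n if n else 0.0
        self.macro_f = sum(r.f_measure for r in self.records) / n if n else 0.0


def _score_pairs(clusters: Sequence[Cluster], groupings: Sequence[ReferenceGrouping]):
    """F/overlap scores for every (cluster, grouping) pair."""
    scores = {}
    for cluster in clusters:
        for grouping in groupings:
            p, r, f = prf(cluster.member_term_ids, grouping.member_term_ids)
            common = len(cluster.member_term_ids & grouping.member_term_ids)
            scores[cluster.cluster_id, grouping.group_id] = (p, r, f, common)
    return scores


def assign_and_report(
    clusters: Sequence[Cluster], groupings: Sequence[ReferenceGrouping]
) -> EvaluationReport:
    """Max-F assignment of clusters to groupings, then per-grouping scoring.

    Ties on F go to the grouping sharing more terms with the cluster, then
    to the lexicographically smaller group id.  Groupings left without an
    assigned cluster are scored against the overall best-F cluster and
    flagged as fallback records.
    """
    if not clusters or not groupings:
        raise ValidationError("need at least one cluster and one grouping")
    scores = _score_pairs(clusters, groupings)

    assigned: dict[str, list[Cluster]] = {g.group_id: [] for g in groupings}
    for cluster in clusters:
        # max F, ties by larger overlap, then by smaller group id
        best = min(
            groupings,
            key=lambda g: (
                -scores[cluster.cluster_id, g.group_id][2],
                -scores[cluster.cluster_id, g.group_id][3],
                g.group_id,
            ),
        )
        assigned[best.group_id].append(cluster)

    records = []
    for grouping in sorted(groupings, key=lambda g: g.group_id):
        pool = assigned[grouping.group_id]
        fallback = not pool
        if fallback:
            pool = list(clusters)
        best_cluster = min(
            pool,
            key=lambda c: (-scores[c.cluster_id, grouping.group_id][2], c.cluster_id),
        )
        p, r, f, common = scores[best_cluster.cluster_id, grouping.group_id]
        records.append(
            EvaluationRecord(
                group_id=grouping.group_id,
                best_cluster_id=best_cluster.cluster_id,
                n_group=len(grouping.member_term_ids),
                n_cluster=len(best_cluster.member_term_ids),
                n_common=common,
                precision=p,
                recall=r,
                f_measure=f,
                fallback=fallback,
            )
        )
    return EvaluationReport(records=records)


def baseline_hlt(terminology: Terminology) -> list[Cluster]:
    """Baseline clusters: one per HLT term, holding its direct PT children.

    This is the standard grouping practice over the native hierarchy; a PT
    with several HLT parents appears in each parent's cluster.
    """
    clusters = []
    graph = terminology.adr_graph.graph  # child -> parent
    hlts = sorted(
        t.term_id for t in terminology.terms.values() if t.level is Level.HLT
    )
    for counter, hlt in enumerate(hlts):
        members = frozenset(
            child
            for child in graph.predecessors(hlt)
            if terminology.terms[child].level is Level.PT
        )
        if members:
            clusters.append(
                Cluster(f"hlt{counter:05d}", members, ClusterMethod.STRUCTURING,
                        provenance=(hlt,))
            )
    return clusters


def cross_validate(
    matrix,
    groupings: Sequence[ReferenceGrouping],
    threshold_grid: Sequence[float],
    n_folds: int = 10,
    seed: int = 0,
    cluster_config: ClusterConfig | None = None,
) -> float:
    """Select a radius threshold by n-fold cross-validation over groupings.

    The groupings are partitioned into ``n_folds`` seeded folds; in each
    fold the grid value maximising macro-F on that single tuning fold is
    recorded, and the value winning most folds is returned (ties go to the
    smaller threshold).
    """
    if len(groupings) < n_folds:
        raise ValidationError("need at least n_folds groupings")
    if not threshold_grid:
        raise ValidationError("threshold grid must be non-empty")
    base = cluster_config or ClusterConfig()

    clusters_by_theta = {}
    for theta in threshold_grid:
        config = ClusterConfig(
            radius_threshold=theta,
            hac_k=base.hac_k,
            hac_linkage=base.hac_linkage,
            min_cluster_size=base.min_cluster_size,
            merge_overlap=base.merge_overlap,
        )
        clusters_by_theta[theta] = radius_clusters(matrix, config)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groupings))
    folds = [list(order[i::n_folds]) for i in range(n_folds)]

    winners = []
    for fold in folds:
        tuning = [groupings[i] for i in fold]
        best_theta, best_f = None, -1.0
        for theta in sorted(threshold_grid):
            clusters = clusters_by_theta[theta]
            if not clusters:
                f = 0.0
            else:
                f = assign_and_report(clusters, tuning).macro_f
            if f > best_f:
                best_theta, best_f = theta, f
        winners.append(best_theta)

    counts = Counter(winners)
    top = max(counts.values())
    return min(theta for theta, c in counts.items() if c == top)
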