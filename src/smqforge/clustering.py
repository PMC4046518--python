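"""Clustering of terms from distance matrices and relation graphs.

Three cluster builders are provided:

* **radius clustering** — every term is a candidate centre; its cluster is
  the set of terms within a distance threshold (or above a similarity
  threshold).  Non-disjoint by design: a term may fall inside many radii.
* **agglomerative clustering (HAC)** — the dendrogram over the distance
  matrix is cut into ``min(k, n)`` disjoint clusters.
* **graph clustering** — induced hierarchical relations are oriented
  parent -> child; each source vertex (a term with no hierarchical parent)
  yields its forward-reachable set as one cluster, then synonym relations
  pull in the synonyms of the members.

Two merging passes follow: within one cluster set and across the sets
produced by the two strategies, any pair of clusters sharing at least 80%
of the smaller cluster's members (by default) is unioned, repeatedly until
a fixed point — which also absorbs clusters wholly included in larger ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from smqforge.model import RelType, SemanticRelation, ValidationError


class ClusterMethod(str, Enum):
    SD_RADIUS = "SD_RADIUS"
    SD_HAC = "SD_HAC"
    STRUCTURING = "STRUCTURING"
    MERGED = "MERGED"


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    member_term_ids: frozenset[str]
    method: ClusterMethod
    center_term_id: str | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.member_term_ids:
            raise ValidationError(f"cluster {self.cluster_id!r} has no members")
        if self.method is ClusterMethod.SD_RADIUS and (
            self.center_term_id is None or self.center_term_id not in self.member_term_ids
        ):
            raise ValidationError(
                f"radius cluster {self.cluster_id!r} must have a member centre"
            )

    def __len__(self) -> int:
        return len(self.member_term_ids)


@dataclass
class ClusterConfig:
    #: neighbourhood threshold; published defaults: Rada 4, LCH 4.10, Zhong 0.02
    radius_threshold: float = 4.0
    hac_k: int = 300
    hac_linkage: str = "average"
    min_cluster_size: int = 2
    merge_overlap: float = 0.8

    def __post_init__(self) -> None:
        if self.radius_threshold <= 0:
            raise ValidationError("radius_threshold must be positive")
        if self.hac_k < 1:
            raise ValidationError("hac_k must be at least 1")
        if not 0 < self.merge_overlap <= 1:
            raise ValidationError("merge_overlap must lie in (0, 1]")


def radius_clusters(matrix, config: ClusterConfig | None = None) -> list[Cluster]:
    """Non-disjoint neighbourhood clusters, one candidate per centre term.

    For a distance matrix the cluster of centre ``c`` is
    ``{t : d(c, t) <= threshold}``; for a similarity matrix it is
    ``{t : sim(c, t) >= threshold}``.  Exact-duplicate member sets are kept
    once (the lexicographically smallest centre wins) and clusters below
    ``min_cluster_size`` are dropped.
    """
    config = config or ClusterConfig()
    values = matrix.values
    theta = config.radius_threshold
    within = values >= theta if matrix.is_similarity else values <= theta
    ids = matrix.term_ids
    order = np.argsort(np.asarray(ids, dtype=object))
    clusters: list[Cluster] = []
    seen: set[frozenset[str]] = set()
    counter = 0
    for i in order:
        members = frozenset(ids[j] for j in np.flatnonzero(within[i]))
        if len(members) < config.min_cluster_size or members in seen:
            continue
        seen.add(members)
        clusters.append(
            Cluster(f"r{counter:05d}", members, ClusterMethod.SD_RADIUS, center_term_id=ids[i])
        )
        counter += 1
    return clusters


def hac_clusters(matrix, config: ClusterConfig | None = None) -> list[Cluster]:
    """Cut the agglomerative dendrogram into ``min(hac_k, n)`` disjoint clusters.

    Similarity matrices are converted to distances as ``max_sim - sim``;
    unreachable pairs (infinite distance) are replaced by a value beyond
    the largest finite distance so they are merged last.
    """
    config = config or ClusterConfig()
    values = np.array(matrix.values, dtype=float)
    if matrix.is_similarity:
        finite = values[np.isfinite(values)]
        top = finite.max() if finite.size else 1.0
        values = top - values
    np.fill_diagonal(values, 0.0)
    finite = values[np.isfinite(values)]
    ceiling = (finite.max() if finite.size else 1.0) * 2 + 1
    values[~np.isfinite(values)] = ceiling
    n = len(matrix.term_ids)
    k = min(config.hac_k, n)
    if n == 1:
        labels = np.array([1])
    else:
        linkage = sch.linkage(squareform(values, checks=False), method=config.hac_linkage)
        labels = sch.fcluster(linkage, t=k, criterion="maxclust")
    clusters = []
    for value in sorted(set(labels)):
        members = frozenset(
            matrix.term_ids[i] for i in np.flatnonzero(labels == value)
        )
        clusters.append(Cluster(f"h{value:05d}", members, ClusterMethod.SD_HAC))
    return clusters


def graph_clusters(
    relations: Iterable[SemanticRelation], min_cluster_size: int = 1
) -> list[Cluster]:
    """Clusters from the induced relation graph.

    Hierarchical relations (stored child -> parent) are oriented
    parent -> child; every source vertex (no hierarchical parent) emits its
    forward-reachable set as one cluster.  Synonymy relations then augment
    each cluster: any term connected by a chain of synonym edges to a
    member joins it.  The result is non-disjoint.
    """
    hierarchy = nx.DiGraph()
    synonym = nx.Graph()
    for rel in relations:
        if rel.rel_type is RelType.HIERARCHICAL:
            hierarchy.add_edge(rel.target_term_id, rel.source_term_id)  # parent -> child
        else:
            synonym.add_edge(rel.source_term_id, rel.target_term_id)
    clusters = []
    counter = 0
    sources = [n for n in sorted(hierarchy.nodes) if hierarchy.in_degree(n) == 0]
    for source in sources:
        members = set(nx.descendants(hierarchy, source)) | {source}
        frontier = list(members)
        while frontier:
            node = frontier.pop()
            if node not in synonym:
                continue
            for neighbour in synonym.neighbors(node):
                if neighbour not in members:
                    members.add(neighbour)
                    frontier.append(neighbour)
        if len(members) < min_cluster_size:
            continue
        clusters.append(
            Cluster(f"g{counter:05d}", frozenset(members), ClusterMethod.STRUCTURING)
        )
        counter += 1
    return clusters


def _overlap(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / min(len(a), len(b))


def _merge_fixpoint(clusters: Sequence[Cluster], threshold: float) -> list[Cluster]:
    """Union clusters pairwise while any pair overlaps at >= threshold.

    Pairs are processed by descending overlap (ties by cluster id), which
    makes the fixed point deterministic; merged clusters carry both
    parents' ids as provenance.
    """
    pool: dict[str, Cluster] = {c.cluster_id: c for c in clusters}
    if len(pool) != len(clusters):
        raise ValidationError("cluster ids must be unique before merging")
    counter = 0
    while True:
        best = None
        ids = sorted(pool)
        for i, id_a in enumerate(ids):
            a = pool[id_a]
            for id_b in ids[i + 1:]:
                b = pool[id_b]
                ov = _overlap(a.member_term_ids, b.member_term_ids)
                if ov >= threshold:
                    key = (-ov, id_a, id_b)
                    if best is None or key < best[0]:
                        best = (key, a, b)
        if best is None:
            return [pool[i] for i in sorted(pool)]
        _, a, b = best
        del pool[a.cluster_id], pool[b.cluster_id]
        merged = Cluster(
            f"m{counter:05d}" if f"m{counter:05d}" not in pool else f"m{counter:05d}x",
            a.member_term_ids | b.member_term_ids,
            ClusterMethod.MERGED,
            provenance=(a.cluster_id, b.cluster_id),
        )
        counter += 1
        while merged.cluster_id in pool:
            merged = Cluster(
                merged.cluster_id + "x", merged.member_term_ids, merged.method,
                provenance=merged.provenance,
            )
        pool[merged.cluster_id] = merged


def merge_within(clusters: Sequence[Cluster], config: ClusterConfig | None = None) -> list[Cluster]:
    """Merge high-overlap (and included) clusters of one method; idempotent."""
    config = config or ClusterConfig()
    return _merge_fixpoint(clusters, config.merge_overlap)


def merge_across(
    set_a: Sequence[Cluster], set_b: Sequence[Cluster], config: ClusterConfig | None = None
) -> list[Cluster]:
    """Merge clusters across two methods' outputs at the same overlap rule."""
    config = config or ClusterConfig()
    combined = list(set_a) + list(set_b)
    ids = [c.cluster_id for c in combined]
    if len(set(ids)) != len(ids):
        combined = [
            Cluster(
                f"{prefix}:{c.cluster_id}", c.member_term_ids, c.method,
                center_term_id=c.center_term_id, provenance=c.provenance,
            )
            for prefix, clusters in (("a", set_a), ("b", set_b))
            for c in clusters
        ]
    return _merge_fixpoint(combined, config.merge_overlap)
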