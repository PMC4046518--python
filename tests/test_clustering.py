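"""Radius / HAC / graph clustering and overlap merging."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from smqforge.clustering import (
    Cluster,
    ClusterConfig,
    ClusterMethod,
    graph_clusters,
    hac_clusters,
    merge_across,
    merge_within,
    radius_clusters,
)
from smqforge.distance import DistanceConfig, DistanceMatrix
from smqforge.model import MethodTag, RelType, SemanticRelation


def matrix_from(values, ids=None, is_similarity=False):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"t{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids, values, DistanceConfig(), is_similarity=is_similarity)


def random_distance_matrix(rng, n):
    values = rng.uniform(0, 10, size=(n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return matrix_from(values)


class TestRadius:
    def test_threshold_below_everything_gives_no_clusters_at_min_size_two(self):
        matrix = matrix_from([[0, 5, 6], [5, 0, 7], [6, 7, 0]])
        assert radius_clusters(matrix, ClusterConfig(radius_threshold=1)) == []

    def test_threshold_above_maximum_gives_one_full_cluster(self):
        matrix = matrix_from([[0, 5, 6], [5, 0, 7], [6, 7, 0]])
        clusters = radius_clusters(matrix, ClusterConfig(radius_threshold=10))
        assert len(clusters) == 1
        assert clusters[0].member_term_ids == frozenset({"t0", "t1", "t2"})
        assert clusters[0].center_term_id in clusters[0].member_term_ids

    def test_identical_terms_zero_matrix(self):
        matrix = matrix_from([[0, 0], [0, 0]])
        clusters = radius_clusters(matrix, ClusterConfig(radius_threshold=1))
        assert len(clusters) == 1  # duplicate member sets deduplicated

    def test_similarity_matrix_uses_lower_bound(self):
        matrix = matrix_from([[5, 4.2], [4.2, 5]], is_similarity=True)
        clusters = radius_clusters(matrix, ClusterConfig(radius_threshold=4.10))
        assert clusters and clusters[0].member_term_ids == frozenset({"t0", "t1"})

    def test_membership_matches_row_scan_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(3, 20))
            matrix = random_distance_matrix(rng, n)
            theta = float(rng.uniform(0, 10))
            clusters = radius_clusters(
                matrix, ClusterConfig(radius_threshold=theta, min_cluster_size=1)
            )
            expected = set()
            for i in range(n):
                members = frozenset(
                    matrix.term_ids[j] for j in range(n) if matrix.values[i, j] <= theta
                )
                expected.add(members)
            assert {c.member_term_ids for c in clusters} == expected

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(8)
        matrix = random_distance_matrix(rng, 12)
        perm = rng.permutation(12)
        permuted = DistanceMatrix(
            [matrix.term_ids[i] for i in perm],
            matrix.values[np.ix_(perm, perm)],
            matrix.config,
        )
        config = ClusterConfig(radius_threshold=4)
        original = {c.member_term_ids for c in radius_clusters(matrix, config)}
        shuffled = {c.member_term_ids for c in radius_clusters(permuted, config)}
        assert original == shuffled


class TestHAC:
    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        matrix = random_distance_matrix(rng, 6)
        clusters = hac_clusters(matrix, ClusterConfig(hac_k=6))
        assert sorted(len(c) for c in clusters) == [1] * 6

    def test_k_one_gives_single_cluster(self):
        rng = np.random.default_rng(2)
        matrix = random_distance_matrix(rng, 6)
        clusters = hac_clusters(matrix, ClusterConfig(hac_k=1))
        assert len(clusters) == 1
        assert clusters[0].member_term_ids == frozenset(matrix.term_ids)

    def test_two_well_separated_triples(self):
        # blocks at distance 1 inside, 50 across
        values = np.full((6, 6), 50.0)
        for block in ((0, 1, 2), (3, 4, 5)):
            for i in block:
                for j in block:
                    values[i, j] = 0.0 if i == j else 1.0
        matrix = matrix_from(values)
        clusters = hac_clusters(matrix, ClusterConfig(hac_k=2))
        assert {c.member_term_ids for c in clusters} == {
            frozenset({"t0", "t1", "t2"}), frozenset({"t3", "t4", "t5"})
        }

    def test_output_is_partition(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 25))
            k = int(rng.integers(1, 30))
            matrix = random_distance_matrix(rng, n)
            clusters = hac_clusters(matrix, ClusterConfig(hac_k=k))
            assert len(clusters) == min(k, n)
            all_members = [t for c in clusters for t in c.member_term_ids]
            assert sorted(all_members) == sorted(matrix.term_ids)  # disjoint + covering


def rel(child, parent):
    return SemanticRelation.make(child, parent, RelType.HIERARCHICAL, MethodTag.LEX_INCLUSION)


def syn(a, b):
    return SemanticRelation.make(a, b, RelType.SYNONYMY, MethodTag.COMPOSITIONAL)


class TestGraphClusters:
    def test_single_chain_seeded_at_source(self):
        relations = [rel("muscle pain", "pain"), rel("left muscle pain", "muscle pain")]
        clusters = graph_clusters(relations)
        assert len(clusters) == 1
        assert clusters[0].member_term_ids == frozenset(
            {"pain", "muscle pain", "left muscle pain"}
        )

    def test_synonym_augmentation(self):
        relations = [rel("muscle pain", "pain"), syn("muscle pain", "muscle ache")]
        clusters = graph_clusters(relations)
        assert clusters[0].member_term_ids == frozenset({"pain", "muscle pain", "muscle ache"})

    def test_shared_descendant_in_both_clusters(self):
        relations = [rel("c", "a"), rel("c", "b")]
        clusters = graph_clusters(relations)
        members = {c.member_term_ids for c in clusters}
        assert members == {frozenset({"a", "c"}), frozenset({"b", "c"})}

    def test_reachability_oracle_on_random_dags(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(3, 10))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[j], nodes[i])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            if not edges:
                continue
            relations = [rel(child, parent) for child, parent in edges]
            clusters = graph_clusters(relations)
            # oracle: forward closure parent->child by repeated expansion
            children = {}
            for child, parent in edges:
                children.setdefault(parent, set()).add(child)
            involved = {x for e in edges for x in e}
            with_parent = {child for child, _ in edges}
            expected = set()
            for source in involved - with_parent:
                closure = {source}
                while True:
                    new = {c for m in closure for c in children.get(m, ())} - closure
                    if not new:
                        break
                    closure |= new
                expected.add(frozenset(closure))
            assert {c.member_term_ids for c in clusters} == expected


def cluster(cid, members, method=ClusterMethod.STRUCTURING):
    return Cluster(cid, frozenset(members), method)


class TestMerging:
    def test_identical_clusters_merge_to_one(self):
        merged = merge_within([cluster("a", {"x", "y"}), cluster("b", {"x", "y"})])
        assert len(merged) == 1
        assert merged[0].method is ClusterMethod.MERGED
        assert set(merged[0].provenance) == {"a", "b"}

    def test_disjoint_clusters_unchanged(self):
        clusters = [cluster("a", {"x", "y"}), cluster("b", {"u", "v"})]
        assert merge_within(clusters) == clusters

    def test_inclusive_threshold_boundary(self):
        big = cluster("big", {f"x{i}" for i in range(6)} | {"c1", "c2", "c3", "c4"})
        small = cluster("small", {"c1", "c2", "c3", "c4", "z"})
        merged = merge_within([big, small])  # overlap 4/5 = 0.8 >= 0.8
        assert len(merged) == 1
        assert merged[0].member_term_ids == big.member_term_ids | small.member_term_ids
        below = cluster("below", {"c1", "c2", "c3", "w", "z"})  # overlap 3/5
        assert len(merge_within([big, below])) == 2

    def test_subset_clusters_absorbed(self):
        merged = merge_within([cluster("a", {"x", "y", "z"}), cluster("b", {"x", "y"})])
        assert len(merged) == 1
        assert merged[0].member_term_ids == frozenset({"x", "y", "z"})

    def test_merge_within_idempotent(self):
        rng = np.random.default_rng(6)
        universe = [f"t{i}" for i in range(12)]
        for _ in range(50):
            clusters = [
                cluster(
                    f"c{j}",
                    {universe[k] for k in rng.choice(12, rng.integers(1, 8), replace=False)},
                )
                for j in range(int(rng.integers(2, 8)))
            ]
            once = merge_within(clusters)
            twice = merge_within(once)
            assert {c.member_term_ids for c in once} == {c.member_term_ids for c in twice}
            assert len(once) == len(twice)

    def test_merge_across_combines_methods(self):
        sd = [Cluster("s1", frozenset({"a", "b", "c"}), ClusterMethod.SD_RADIUS,
                      center_term_id="a")]
        struct = [cluster("g1", {"a", "b"}), cluster("g2", {"x", "y"})]
        merged = merge_across(sd, struct)
        members = {c.member_term_ids for c in merged}
        assert members == {frozenset({"a", "b", "c"}), frozenset({"x", "y"})}
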