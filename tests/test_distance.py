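"""Semantic distance measures: closed forms, oracles and matrix semantics."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from smqforge.distance import (
    DistanceConfig,
    Measure,
    MissingAxisPolicy,
    build_distance_matrix,
    combined_distance,
    lch_similarity,
    rada_distance,
    shortest_path_edges,
    zhong_distance,
)
from smqforge.model import AxisGraph, NoPathError

from conftest import chain_axis, make_terminology


def random_dag(rng, n: int, p: float = 0.35) -> AxisGraph:
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[j], nodes[i])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return AxisGraph("x", nodes, edges)


def bfs_oracle(axis: AxisGraph, a: str, b: str) -> float:
    """Plain breadth-first search on the undirected adjacency, for cross-checking."""
    adjacency: dict[str, set[str]] = {n: set() for n in axis.nodes}
    for child, parent in axis.isa_edges:
        adjacency[child].add(parent)
        adjacency[parent].add(child)
    queue, seen = deque([(a, 0)]), {a}
    while queue:
        node, dist = queue.popleft()
        if node == b:
            return dist
        for neighbour in adjacency[node]:
            if neighbour not in seen:
                seen.add(neighbour)
                queue.append((neighbour, dist + 1))
    return math.inf


def zhong_oracle(axis: AxisGraph, a: str, b: str, k: float) -> float:
    """Brute-force minimisation over every common ancestor."""
    if a == b:
        return 0.0

    def up(node):
        out = {node}
        frontier = [node]
        while frontier:
            current = frontier.pop()
            for child, parent in axis.isa_edges:
                if child == current and parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out

    def milestone(node):
        return 1.0 / (2.0 * k ** axis.depth(node))

    common = up(a) & up(b)
    if not common:
        return math.inf
    return min(2 * milestone(c) - milestone(a) - milestone(b) for c in common)


class TestShortestPath:
    def test_identity_and_direct_edge(self):
        axis = chain_axis("x", ["root", "mid", "leaf"])
        assert shortest_path_edges(axis, "leaf", "leaf") == 0
        assert shortest_path_edges(axis, "leaf", "mid") == 1
        assert shortest_path_edges(axis, "leaf", "root") == 2

    def test_path_through_common_ancestor(self):
        axis = AxisGraph("x", ["r", "a", "b"], [("a", "r"), ("b", "r")])
        assert shortest_path_edges(axis, "a", "b") == 2

    def test_absent_node_raises(self):
        axis = chain_axis("x", ["r", "a"])
        with pytest.raises(KeyError):
            shortest_path_edges(axis, "a", "ghost")

    def test_disconnected_is_infinite(self):
        axis = AxisGraph("x", ["a", "b"], [])
        assert math.isinf(shortest_path_edges(axis, "a", "b"))

    def test_matches_bfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(20_240_101)
        checks = 0
        while checks < 250:
            axis = random_dag(rng, int(rng.integers(3, 10)))
            nodes = sorted(axis.nodes)
            a, b = (nodes[i] for i in rng.choice(len(nodes), 2, replace=True))
            assert shortest_path_edges(axis, a, b) == bfs_oracle(axis, a, b)
            checks += 1


class TestMeasures:
    def test_rada_is_identity_on_sp(self):
        assert rada_distance(0) == 0
        assert rada_distance(1) == 1
        assert rada_distance(4) == 4

    def test_lch_closed_form(self):
        assert lch_similarity(0, 8, 2) == pytest.approx(4.0)

    def test_lch_monotone_decreasing_in_sp(self):
        for depth in (1, 5, 14):
            assert lch_similarity(3, depth) < lch_similarity(1, depth)

    def test_lch_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            sp = int(rng.integers(0, 30))
            depth = int(rng.integers(1, 15))
            base = float(rng.uniform(1.5, 10))
            assert lch_similarity(sp, depth, base) == pytest.approx(
                -math.log((sp + 1) / (2 * depth), base)
            )

    def test_zhong_identity_and_root_child(self):
        axis = chain_axis("x", ["root", "child"])
        assert zhong_distance(axis, "child", "child") == 0.0
        assert zhong_distance(axis, "root", "child", k=2) == pytest.approx(0.25)

    def test_zhong_matches_exhaustive_ancestor_oracle(self):
        rng = np.random.default_rng(99)
        checks = 0
        while checks < 250:
            axis = random_dag(rng, int(rng.integers(3, 9)), p=0.45)
            nodes = sorted(axis.nodes)
            a, b = (nodes[i] for i in rng.choice(len(nodes), 2, replace=True))
            k = float(rng.uniform(2, 4))
            got = zhong_distance(axis, a, b, k)
            expected = zhong_oracle(axis, a, b, k)
            if math.isinf(expected):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(expected)
            checks += 1

    def test_zhong_bounded_on_connected_dags(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            axis = random_dag(rng, int(rng.integers(3, 9)), p=0.9)
            nodes = sorted(axis.nodes)
            for a in nodes:
                for b in nodes:
                    d = zhong_distance(axis, a, b, k=2)
                    if math.isfinite(d):
                        assert 0 <= d < 1


def two_axis_fixture():
    """Two terms with per-axis shortest paths 4 (ADR), 0 (D) and 10 (B)."""
    d_axis = chain_axis("D", ["droot", "dnode"])
    b_left = [f"bl{i}" for i in range(5)]
    b_right = [f"br{i}" for i in range(5)]
    b_axis = AxisGraph(
        "B",
        ["broot"] + b_left + b_right,
        [(b_left[0], "broot"), (b_right[0], "broot")]
        + [(b_left[i + 1], b_left[i]) for i in range(4)]
        + [(b_right[i + 1], b_right[i]) for i in range(4)],
    )
    from smqforge.model import Level

    return make_terminology(
        {"t1": "abdominal abscess", "t2": "pharyngeal abscess"},
        adr_edges=[("m1", "root"), ("m2", "root"), ("t1", "m1"), ("t2", "m2")],
        extra_terms={
            "root": ("root", Level.OTHER),
            "m1": ("mid one", Level.OTHER),
            "m2": ("mid two", Level.OTHER),
        },
        aux_axes={"D": d_axis, "B": b_axis},
        definitions={
            "t1": {"D": "dnode", "B": "bl4"},
            "t2": {"D": "dnode", "B": "br4"},
        },
    )


class TestCombined:
    def test_weighted_worked_example(self):
        """sp_ADR=4, sp_D=0, sp_B=10 with weights (1, 2, 1) combine to 3.5."""
        terminology = two_axis_fixture()
        assert shortest_path_edges(terminology.adr_graph, "t1", "t2") == 4
        assert shortest_path_edges(terminology.aux_axes["D"], "dnode", "dnode") == 0
        assert shortest_path_edges(terminology.aux_axes["B"], "bl4", "br4") == 10
        config = DistanceConfig(measure=Measure.RADA)
        assert combined_distance("t1", "t2", terminology, config) == pytest.approx(3.5)

    def test_without_definitions_reduces_to_adr(self):
        terminology = two_axis_fixture()
        config = DistanceConfig(measure=Measure.RADA, use_formal_definitions=False)
        assert combined_distance("t1", "t2", terminology, config) == 4.0

    def test_equal_weights_give_arithmetic_mean(self):
        terminology = two_axis_fixture()
        config = DistanceConfig(
            measure=Measure.RADA, axis_weights={"ADR": 1.0, "D": 1.0, "B": 1.0}
        )
        assert combined_distance("t1", "t2", terminology, config) == pytest.approx(
            (4 + 0 + 10) / 3
        )

    def test_identical_terms_have_zero_distance(self):
        terminology = two_axis_fixture()
        config = DistanceConfig(measure=Measure.RADA)
        assert combined_distance("t1", "t1", terminology, config) == 0.0

    def test_missing_binding_renormalizes_or_fails(self):
        terminology = two_axis_fixture()
        del terminology.definitions["t2"].axis_bindings["B"]
        config = DistanceConfig(measure=Measure.RADA)
        # axes left: ADR (w=1, sp=4) and D (w=2, sp=0)
        assert combined_distance("t1", "t2", terminology, config) == pytest.approx(4 / 3)
        config_fail = DistanceConfig(
            measure=Measure.RADA, missing_axis_policy=MissingAxisPolicy.FAIL
        )
        with pytest.raises(NoPathError):
            combined_distance("t1", "t2", terminology, config_fail)


class TestMatrix:
    def test_symmetry_zero_diagonal_all_measures(self):
        terminology = two_axis_fixture()
        for measure in Measure:
            config = DistanceConfig(measure=measure)
            matrix = build_distance_matrix(terminology, ["t1", "t2"], config)
            assert np.allclose(matrix.values, matrix.values.T)
            if not matrix.is_similarity:
                assert np.all(np.diag(matrix.values) == 0)
            else:
                # similarity diagonal is the per-term maximum
                assert (np.diag(matrix.values) >= matrix.values.max(axis=1) - 1e-12).all()

    def test_matrix_matches_entrywise_combined_distance(self):
        rng = np.random.default_rng(11)
        from smqforge.simulate import GeneratorConfig, generate

        terminology, _, _, _ = generate(
            GeneratorConfig(seed=3, n_soc=2, n_hlgt_per_soc=2, n_hlt_per_hlgt=2,
                            n_pt_per_hlt=4, n_groupings=3, noise=False)
        )
        subset = terminology.pt_ids()[:25]
        for measure in Measure:
            config = DistanceConfig(measure=measure)
            matrix = build_distance_matrix(terminology, subset, config)
            for _ in range(40):
                i, j = rng.integers(0, len(subset), 2)
                expected = (
                    combined_distance(subset[i], subset[j], terminology, config)
                    if i != j or measure is Measure.LCH
                    else 0.0
                )
                assert matrix.values[i, j] == pytest.approx(expected)

    def test_rada_triangle_inequality_on_connected_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            axis = random_dag(rng, int(rng.integers(4, 9)), p=0.9)
            nodes = sorted(axis.nodes)
            sp = {
                (a, b): shortest_path_edges(axis, a, b) for a in nodes for b in nodes
            }
            for a in nodes:
                for b in nodes:
                    for c in nodes:
                        if all(math.isfinite(sp[x]) for x in ((a, b), (b, c), (a, c))):
                            assert sp[a, c] <= sp[a, b] + sp[b, c]

    def test_closest_pair_has_smallest_off_diagonal(self):
        """Terms adjacent in the hierarchy beat distant ones, as in a real
        distance matrix where e.g. two ulcer terms are 1 apart and an
        unrelated procedure term is 10+ away."""
        adr = AxisGraph(
            "ADR",
            ["root", "gi", "proc", "gastric ulcer", "gastrointestinal ulcer", "biopsy"],
            [
                ("gi", "root"), ("proc", "root"),
                ("gastrointestinal ulcer", "gi"),
                ("gastric ulcer", "gastrointestinal ulcer"),
                ("biopsy", "proc"),
            ],
        )
        from smqforge.model import Level, Term, Terminology

        terms = {n: Term(n, n, Level.PT if " " in n or n == "biopsy" else Level.OTHER)
                 for n in adr.nodes}
        terminology = Terminology(terms=terms, adr_graph=adr)
        config = DistanceConfig(measure=Measure.RADA, use_formal_definitions=False)
        subset = ["gastric ulcer", "gastrointestinal ulcer", "biopsy"]
        matrix = build_distance_matrix(terminology, subset, config)
        assert matrix.value("gastric ulcer", "gastrointestinal ulcer") == 1
        off_diagonal = matrix.values[~np.eye(3, dtype=bool)]
        assert matrix.value("gastric ulcer", "gastrointestinal ulcer") == off_diagonal.min()
        assert matrix.value("gastric ulcer", "biopsy") > 1
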