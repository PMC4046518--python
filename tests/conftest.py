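"""Shared fixtures: tiny hand-built terminologies and the seeded benchmark."""

from __future__ import annotations

import pytest

from smqforge.distance import DistanceConfig, build_distance_matrix
from smqforge.model import AxisGraph, FormalDefinition, Level, Term, Terminology
from smqforge.simulate import GeneratorConfig, generate
from smqforge.structuring import structure_terminology


def make_terminology(
    pt_labels: dict[str, str],
    adr_edges: list[tuple[str, str]] = (),
    extra_terms: dict[str, tuple[str, Level]] | None = None,
    aux_axes: dict[str, AxisGraph] | None = None,
    definitions: dict[str, dict[str, str]] | None = None,
) -> Terminology:
    """Build a terminology from PT labels plus optional scaffolding."""
    terms = {tid: Term(tid, label, Level.PT) for tid, label in pt_labels.items()}
    for tid, (label, level) in (extra_terms or {}).items():
        terms[tid] = Term(tid, label, level)
    return Terminology(
        terms=terms,
        adr_graph=AxisGraph("ADR", terms.keys(), adr_edges),
        aux_axes=aux_axes or {},
        definitions={
            tid: FormalDefinition(tid, dict(bindings))
            for tid, bindings in (definitions or {}).items()
        },
    )


def chain_axis(axis_id: str, nodes: list[str]) -> AxisGraph:
    """A simple chain hierarchy: nodes[0] is the root."""
    edges = [(nodes[i + 1], nodes[i]) for i in range(len(nodes) - 1)]
    return AxisGraph(axis_id, nodes, edges)


@pytest.fixture(scope="session")
def benchmark():
    """The default seeded synthetic benchmark, generated once per session."""
    terminology, lexicon, groupings, truth = generate(GeneratorConfig(seed=42))
    return {
        "terminology": terminology,
        "lexicon": lexicon,
        "groupings": groupings,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark):
    """Combined Rada distance matrix (with formal definitions) on the benchmark."""
    return build_distance_matrix(benchmark["terminology"], None, DistanceConfig())


@pytest.fixture(scope="session")
def benchmark_relations(benchmark):
    return structure_terminology(benchmark["terminology"], [benchmark["lexicon"]])
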