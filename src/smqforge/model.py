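"""Domain model for MedDRA-like terminologies.

A terminology is a set of levelled terms (SOC > HLGT > HLT > PT > LLT)
linked by is-a edges, optionally enriched with *formal definitions*: a
decomposition of each term onto auxiliary semantic axes (conventionally
``D`` for the abnormality/disorder type and ``B`` for the anatomical
localisation), each axis carrying its own is-a hierarchy.  All graphs are
DAGs with edges stored child -> parent; multiple parents are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx


class Level(str, Enum):
    """Hierarchical level of a term (MedDRA convention, plus OTHER)."""

    SOC = "SOC"
    HLGT = "HLGT"
    HLT = "HLT"
    PT = "PT"
    LLT = "LLT"
    OTHER = "OTHER"


class RelType(str, Enum):
    HIERARCHICAL = "HIERARCHICAL"
    SYNONYMY = "SYNONYMY"


class MethodTag(str, Enum):
    LEX_INCLUSION = "LEX_INCLUSION"
    VARIANT = "VARIANT"
    COMPOSITIONAL = "COMPOSITIONAL"
    LEXICON = "LEXICON"


class ValidationError(ValueError):
    """Raised when an input violates a model invariant."""


class NoPathError(LookupError):
    """Raised under the FAIL policy when two nodes are not connected."""


def normalize_label(label: str) -> str:
    """Whitespace-normalised, case-folded form used for label matching."""
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class Term:
    term_id: str
    label: str
    level: Level = Level.PT

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValidationError("term_id must be non-empty")
        if not self.label or not self.label.strip():
            raise ValidationError(f"term {self.term_id!r}: label must be non-empty")


class AxisGraph:
    """An is-a hierarchy for one semantic axis.

    Edges are directed child -> parent.  The graph must be acyclic; nodes
    may have several parents (SNOMED-like).  ``depth`` of a node is the
    length of the longest root-to-node path, which is monotone along
    ancestry even in a DAG; ``max_depth`` is the depth of the deepest node
    (at least 1, so that depth-normalised similarity is always defined).
    """

    def __init__(self, axis_id: str, nodes: Iterable[str], isa_edges: Iterable[tuple[str, str]]):
        self.axis_id = axis_id
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for child, parent in isa_edges:
            for endpoint in (child, parent):
                if endpoint not in g:
                    raise ValidationError(
                        f"axis {axis_id!r}: edge ({child!r}, {parent!r}) references "
                        f"undeclared node {endpoint!r}"
                    )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"axis {axis_id!r}: is-a edges contain a cycle: {cycle}")
        self._graph = g
        self._undirected = g.to_undirected(as_view=True)
        self._recompute_depths()

    def _recompute_depths(self) -> None:
        # longest root-to-node path; computed in reverse topological order
        # over the parent->child orientation.
        depth: dict[str, int] = {}
        # edges run child -> parent, so parents come after children in the
        # topological order; traverse it reversed so parents resolve first
        for node in reversed(list(nx.topological_sort(self._graph))):
            parents = list(self._graph.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        self._depth = depth
        self.max_depth = max(1, max(depth.values(), default=0))

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def undirected(self) -> nx.Graph:
        return self._undirected

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def isa_edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges)

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def depth(self, node: str) -> int:
        """Longest root-to-node path length."""
        return self._depth[node]

    def ancestors_or_self(self, node: str) -> set[str]:
        """All nodes reachable via child->parent edges, including the node."""
        return nx.descendants(self._graph, node) | {node}

    def add_edges(self, edges: Iterable[tuple[str, str]]) -> None:
        for child, parent in edges:
            self._graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise ValidationError(f"axis {self.axis_id!r}: added edges create a cycle")
        self._recompute_depths()


@dataclass
class FormalDefinition:
    """Binding of one term to nodes of the auxiliary axes (e.g. D, B)."""

    term_id: str
    axis_bindings: dict[str, str] = field(default_factory=dict)


@dataclass
class Terminology:
    """A levelled terminology with its term hierarchy and optional axes."""

    terms: dict[str, Term]
    adr_graph: AxisGraph
    aux_axes: dict[str, AxisGraph] = field(default_factory=dict)
    definitions: dict[str, FormalDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.adr_graph.nodes:
            if node not in self.terms:
                raise ValidationError(f"ADR graph node {node!r} is not a declared term")
        for term_id, definition in self.definitions.items():
            if term_id not in self.terms:
                raise ValidationError(f"definition references unknown term {term_id!r}")
            for axis_id, node in definition.axis_bindings.items():
                axis = self.aux_axes.get(axis_id)
                if axis is None:
                    raise ValidationError(
                        f"definition of {term_id!r} references unknown axis {axis_id!r}"
                    )
                if node not in axis:
                    raise ValidationError(
                        f"definition of {term_id!r}: node {node!r} absent from axis {axis_id!r}"
                    )

    def pt_ids(self) -> list[str]:
        """PT-level term ids in sorted order (the working vocabulary)."""
        return sorted(t.term_id for t in self.terms.values() if t.level is Level.PT)

    def label_index(self, level: Level | None = Level.PT) -> dict[str, str]:
        """Map normalised label -> term_id, optionally restricted to a level.

        On duplicate labels the smallest term_id wins (deterministic).
        """
        index: dict[str, str] = {}
        for term_id in sorted(self.terms):
            term = self.terms[term_id]
            if level is not None and term.level is not level:
                continue
            index.setdefault(normalize_label(term.label), term_id)
        return index


@dataclass
class SynonymLexicon:
    """Unordered synonym pairs from an external lexical resource."""

    pairs: set[frozenset[str]] = field(default_factory=set)
    source_tag: str = ""

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], source_tag: str = "") -> "SynonymLexicon":
        out: set[frozenset[str]] = set()
        for a, b in pairs:
            a, b = normalize_label(a), normalize_label(b)
            if a and b and a != b:
                out.add(frozenset((a, b)))
        return cls(pairs=out, source_tag=source_tag)

    def synonym_map(self) -> dict[str, set[str]]:
        """Map each word/phrase to the set of its synonyms."""
        out: dict[str, set[str]] = {}
        for pair in self.pairs:
            a, b = sorted(pair)
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return frozenset((normalize_label(a), normalize_label(b))) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SemanticRelation:
    """A typed term-term relation with method provenance.

    HIERARCHICAL relations are directed child -> parent (source is the more
    specific term).  SYNONYMY relations are undirected and stored with the
    endpoints in lexicographic order, so that equal relations compare equal.
    """

    source_term_id: str
    target_term_id: str
    rel_type: RelType
    method_tag: MethodTag

    def __post_init__(self) -> None:
        if self.source_term_id == self.target_term_id:
            raise ValidationError("relation endpoints must be distinct")
        if self.rel_type is RelType.SYNONYMY and self.source_term_id > self.target_term_id:
            a, b = self.target_term_id, self.source_term_id
            object.__setattr__(self, "source_term_id", a)
            object.__setattr__(self, "target_term_id", b)

    @classmethod
    def make(
        cls,
        source: str,
        target: str,
        rel_type: RelType,
        method_tag: MethodTag,
    ) -> "SemanticRelation":
        if rel_type is RelType.SYNONYMY:
            source, target = sorted((source, target))
        return cls(source, target, rel_type, method_tag)


@dataclass(frozen=True)
class ReferenceGrouping:
    """A reference safety-topic grouping (SMQ-like) used as gold standard."""

    group_id: str
    name: str
    member_term_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_term_ids:
            raise ValidationError(f"grouping {self.group_id!r} has no members")
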