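"""Semantic distance and similarity between terms of a terminology.

Three edge-counting measures over is-a hierarchies are implemented:

* **Rada** — the shortest path ``sp`` between two nodes, counted in edges
  traversed in either direction (all edges weigh 1);
* **Leacock-Chodorow (LCH)** — the depth-normalised similarity
  ``-log((sp + 1) / (2 * max_depth))``, where ``max_depth`` is the depth of
  the deepest node of the hierarchy;
* **Zhong** — a milestone scheme: each node ``n`` carries
  ``m(n) = 1 / (2 * k**depth(n))`` and the distance between ``a`` and ``b``
  is ``(m(ccp) - m(a)) + (m(ccp) - m(b))`` for the common ancestor ``ccp``
  minimising the sum (the deepest common ancestor).

Each measure is computed per axis — on the term (ADR) hierarchy and, when
formal definitions are enabled, on the abnormality (D) and anatomy (B)
axes — and the per-axis values are combined into a unique value by the
weighted mean ``sum_i(W_i * sd(t1_i, t2_i)) / sum_j(W_j)``.  The default
weights are 1 for ADR and B and 2 for D, reflecting the prominence of the
abnormality type.

Disconnected node pairs yield ``inf`` (distances) or ``-inf`` (LCH
similarity) under the default RENORMALIZE policy; the FAIL policy raises
:class:`~smqforge.model.NoPathError` instead.  Axes where either term lacks
a formal-definition binding are dropped and the weights renormalised over
the remaining axes (or an error is raised under FAIL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from smqforge.model import AxisGraph, NoPathError, Terminology, ValidationError

ADR = "ADR"


class Measure(str, Enum):
    RADA = "rada"
    LCH = "lch"
    ZHONG = "zhong"


class MissingAxisPolicy(str, Enum):
    RENORMALIZE = "renormalize"
    FAIL = "fail"


@dataclass
class DistanceConfig:
    measure: Measure = Measure.RADA
    axis_weights: dict[str, float] = field(default_factory=lambda: {ADR: 1.0, "D": 2.0, "B": 1.0})
    use_formal_definitions: bool = True
    log_base: float = 2.0
    zhong_k: float = 2.0
    missing_axis_policy: MissingAxisPolicy = MissingAxisPolicy.RENORMALIZE

    def __post_init__(self) -> None:
        if isinstance(self.measure, str):
            self.measure = Measure(self.measure)
        if isinstance(self.missing_axis_policy, str):
            self.missing_axis_policy = MissingAxisPolicy(self.missing_axis_policy)
        if ADR not in self.axis_weights:
            raise ValidationError("axis ADR must always be enabled")
        if any(w <= 0 for w in self.axis_weights.values()):
            raise ValidationError("axis weights must be strictly positive")
        if self.log_base <= 1:
            raise ValidationError("log_base must exceed 1")
        if self.zhong_k <= 1:
            raise ValidationError("zhong_k must exceed 1")

    @property
    def is_similarity(self) -> bool:
        return self.measure is Measure.LCH


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (or similarity) matrix over term ids."""

    term_ids: list[str]
    values: np.ndarray
    config: DistanceConfig
    is_similarity: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.term_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix dimensions do not match term_ids")

    def index_of(self, term_id: str) -> int:
        return self.term_ids.index(term_id)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])


def shortest_path_edges(axis: AxisGraph, a: str, b: str) -> float:
    """Minimum number of is-a edges connecting ``a`` and ``b``.

    Edges may be traversed in either direction (through common ancestors or
    descendants).  Returns ``inf`` when the nodes are not connected.
    """
    for node in (a, b):
        if node not in axis:
            raise KeyError(f"node {node!r} absent from axis {axis.axis_id!r}")
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(axis.undirected, a, b)
    except nx.NetworkXNoPath:
        return math.inf


def rada_distance(sp: float) -> float:
    """Rada semantic distance: the shortest path itself."""
    if sp < 0:
        raise ValidationError("shortest path must be non-negative")
    return sp


def lch_similarity(sp: float, max_depth: int, log_base: float = 2.0) -> float:
    """Leacock-Chodorow similarity ``-log((sp + 1) / (2 * max_depth))``.

    The node-count convention ``sp + 1`` makes the value finite at
    ``sp = 0`` (identical terms), where it attains its maximum
    ``log(2 * max_depth)``.  Disconnected pairs (``sp = inf``) get ``-inf``.
    """
    if max_depth < 1:
        raise ValidationError("max_depth must be at least 1")
    if math.isinf(sp):
        return -math.inf
    return -math.log((sp + 1) / (2 * max_depth)) / math.log(log_base)


def _milestone(depth: int, k: float) -> float:
    return 1.0 / (2.0 * k**depth)


def zhong_distance(axis: AxisGraph, a: str, b: str, k: float = 2.0) -> float:
    """Zhong milestone distance between two nodes of one axis.

    ``(m(ccp) - m(a)) + (m(ccp) - m(b))`` minimised over common ancestors
    ``ccp``; since milestones strictly decrease with depth this selects the
    deepest common ancestor (ties broken lexicographically).  Lies in
    ``[0, 1)`` for ``k >= 2``; identical nodes get 0; pairs without a common
    ancestor get ``inf``.
    """
    for node in (a, b):
        if node not in axis:
            raise KeyError(f"node {node!r} absent from axis {axis.axis_id!r}")
    if a == b:
        return 0.0
    common = axis.ancestors_or_self(a) & axis.ancestors_or_self(b)
    if not common:
        return math.inf
    ccp = max(common, key=lambda n: (axis.depth(n), n))
    m_ccp = _milestone(axis.depth(ccp), k)
    return (m_ccp - _milestone(axis.depth(a), k)) + (m_ccp - _milestone(axis.depth(b), k))


def _axis_value(
    axis: AxisGraph, a: str, b: str, config: DistanceConfig
) -> float:
    measure = config.measure
    if measure is Measure.ZHONG:
        return zhong_distance(axis, a, b, config.zhong_k)
    sp = shortest_path_edges(axis, a, b)
    if measure is Measure.RADA:
        return rada_distance(sp)
    return lch_similarity(sp, axis.max_depth, config.log_base)


def _enabled_axes(terminology: Terminology, config: DistanceConfig) -> list[str]:
    axes = [ADR]
    if config.use_formal_definitions:
        axes += [a for a in sorted(config.axis_weights) if a != ADR and a in terminology.aux_axes]
    return axes


def combined_distance(t1: str, t2: str, terminology: Terminology, config: DistanceConfig) -> float:
    """Weighted multi-axis distance/similarity between two terms.

    With formal definitions disabled this reduces exactly to the raw
    measure on the ADR hierarchy.
    """
    numerator = 0.0
    denominator = 0.0
    for axis_id in _enabled_axes(terminology, config):
        if axis_id == ADR:
            axis, na, nb = terminology.adr_graph, t1, t2
        else:
            axis = terminology.aux_axes[axis_id]
            na = terminology.definitions.get(t1, None)
            nb = terminology.definitions.get(t2, None)
            na = na.axis_bindings.get(axis_id) if na else None
            nb = nb.axis_bindings.get(axis_id) if nb else None
            if na is None or nb is None:
                if config.missing_axis_policy is MissingAxisPolicy.FAIL:
                    raise NoPathError(
                        f"axis {axis_id!r}: missing formal-definition binding for "
                        f"{t1 if na is None else t2!r}"
                    )
                continue
        value = _axis_value(axis, na, nb, config)
        if math.isinf(value) and config.missing_axis_policy is MissingAxisPolicy.FAIL:
            raise NoPathError(f"axis {axis_id!r}: no path between {na!r} and {nb!r}")
        weight = config.axis_weights[axis_id]
        numerator += weight * value
        denominator += weight
    if denominator == 0:
        raise NoPathError(f"no usable axis for pair ({t1!r}, {t2!r})")
    if math.isinf(numerator):
        return math.inf if not config.is_similarity else -math.inf
    return numerator / denominator


def _pairwise_sp(axis: AxisGraph, nodes: Sequence[str]) -> np.ndarray:
    """All-pairs shortest paths among ``nodes`` on the undirected view."""
    index = {n: i for i, n in enumerate(nodes)}
    out = np.full((len(nodes), len(nodes)), np.inf)
    undirected = axis.undirected
    for i, node in enumerate(nodes):
        lengths = nx.single_source_shortest_path_length(undirected, node)
        for other, dist in lengths.items():
            j = index.get(other)
            if j is not None:
                out[i, j] = dist
    np.fill_diagonal(out, 0.0)
    return out


def _pairwise_zhong(axis: AxisGraph, nodes: Sequence[str], k: float) -> np.ndarray:
    milestones = {n: _milestone(axis.depth(n), k) for n in axis.nodes}
    ancestors = {n: axis.ancestors_or_self(n) for n in nodes}
    n = len(nodes)
    out = np.zeros((n, n))
    for i in range(n):
        a = nodes[i]
        for j in range(i + 1, n):
            b = nodes[j]
            if a == b:
                continue
            common = ancestors[a] & ancestors[b]
            if not common:
                out[i, j] = out[j, i] = np.inf
                continue
            ccp = max(common, key=lambda x: (axis.depth(x), x))
            d = 2 * milestones[ccp] - milestones[a] - milestones[b]
            out[i, j] = out[j, i] = d
    return out


def _axis_matrix(
    axis: AxisGraph, nodes: Sequence[str], config: DistanceConfig
) -> np.ndarray:
    if config.measure is Measure.ZHONG:
        return _pairwise_zhong(axis, nodes, config.zhong_k)
    sp = _pairwise_sp(axis, nodes)
    if config.measure is Measure.RADA:
        return sp
    with np.errstate(divide="ignore"):
        return -np.log((sp + 1) / (2 * axis.max_depth)) / math.log(config.log_base)


def build_distance_matrix(
    terminology: Terminology,
    term_subset: Sequence[str] | None = None,
    config: DistanceConfig | None = None,
) -> DistanceMatrix:
    """Pairwise combined distance/similarity matrix over a term subset.

    ``term_subset`` defaults to all PT-level terms.  The matrix is
    symmetric; for distances the diagonal is 0, for LCH similarity it is
    the per-term maximum (the combined self-similarity).
    """
    config = config or DistanceConfig()
    term_ids = list(term_subset) if term_subset is not None else terminology.pt_ids()
    if not term_ids:
        raise ValidationError("term subset must be non-empty")
    n = len(term_ids)

    weight_sum = np.zeros((n, n))
    weighted = np.zeros((n, n))

    for axis_id in _enabled_axes(terminology, config):
        weight = config.axis_weights[axis_id]
        if axis_id == ADR:
            values = _axis_matrix(terminology.adr_graph, term_ids, config)
            available = np.ones(n, dtype=bool)
        else:
            axis = terminology.aux_axes[axis_id]
            bindings: list[str | None] = []
            for t in term_ids:
                definition = terminology.definitions.get(t)
                node = definition.axis_bindings.get(axis_id) if definition else None
                bindings.append(node if node in axis else None)
            available = np.array([b is not None for b in bindings])
            if config.missing_axis_policy is MissingAxisPolicy.FAIL and not available.all():
                missing = term_ids[int(np.argmin(available))]
                raise NoPathError(f"axis {axis_id!r}: missing binding for {missing!r}")
            used_nodes = sorted({b for b in bindings if b is not None})
            if not used_nodes:
                continue
            node_values = _axis_matrix(axis, used_nodes, config)
            node_index = {nd: i for i, nd in enumerate(used_nodes)}
            idx = np.array([node_index.get(b, 0) for b in bindings])
            values = node_values[np.ix_(idx, idx)]
        mask = np.outer(available, available)
        contribution = np.where(mask, values, 0.0)
        weighted = weighted + weight * contribution
        weight_sum = weight_sum + weight * mask

    if (weight_sum == 0).any():
        raise NoPathError("some term pair has no usable axis under the current policy")
    values = weighted / weight_sum
    if not config.is_similarity:
        np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(term_ids=term_ids, values=values, config=config,
                          is_similarity=config.is_similarity)
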