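"""Readers and writers for the TSV/JSON interchange formats.

All TSV files are UTF-8 with a header row.  Layouts:

* ``terms.tsv`` — term_id, label, level
* ``edges.<axis>.tsv`` — child_id, parent_id
* ``definitions.tsv`` — term_id, axis_id, node_id
* ``lexicon.tsv`` — word_a, word_b
* ``groupings.tsv`` — group_id, name, term_id (one row per member)
* ``relations.tsv`` — source, target, rel_type, method_tag
* ``clusters.json`` — list of objects with cluster_id, method, member_ids
* matrix TSV — header row/column of term ids, numeric cells

Every writer/reader pair round-trips the in-memory model exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from smqforge.model import (
    AxisGraph,
    FormalDefinition,
    Level,
    MethodTag,
    ReferenceGrouping,
    RelType,
    SemanticRelation,
    SynonymLexicon,
    Term,
    Terminology,
    ValidationError,
)

logger = logging.getLogger(__name__)

_ADR_AXIS = "ADR"


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    bad = frame.index[(frame[list(columns)] == "").any(axis=1)]
    if len(bad):
        # +2: one for the header, one for 0-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValidationError(f"{path}: empty required fields on line(s) {lines}")
    return frame


def read_terminology(
    term_table_path: str | Path,
    edge_table_paths: Mapping[str, str | Path],
    definition_table_path: str | Path | None = None,
) -> Terminology:
    """Load and validate a terminology from its TSV tables.

    ``edge_table_paths`` maps an axis id to its edge list; the ``ADR`` axis
    (whose nodes are the term ids themselves) is mandatory, further axes
    (e.g. ``D``, ``B``) carry the formal-definition hierarchies.
    """
    terms_frame = _read_tsv(term_table_path, ("term_id", "label", "level"))
    terms: dict[str, Term] = {}
    for i, row in terms_frame.iterrows():
        if row["term_id"] in terms:
            raise ValidationError(
                f"{term_table_path}: duplicate term_id {row['term_id']!r} on line {i + 2}"
            )
        try:
            level = Level(row["level"])
        except ValueError as exc:
            raise ValidationError(
                f"{term_table_path}: unknown level {row['level']!r} on line {i + 2}"
            ) from exc
        terms[row["term_id"]] = Term(row["term_id"], row["label"], level)

    if _ADR_AXIS not in edge_table_paths:
        raise ValidationError(f"edge_table_paths must include the {_ADR_AXIS!r} axis")

    adr_frame = _read_tsv(edge_table_paths[_ADR_AXIS], ("child_id", "parent_id"))
    adr_edges = list(zip(adr_frame["child_id"], adr_frame["parent_id"]))
    for i, (child, parent) in enumerate(adr_edges):
        for endpoint in (child, parent):
            if endpoint not in terms:
                raise ValidationError(
                    f"{edge_table_paths[_ADR_AXIS]}: line {i + 2} references "
                    f"undeclared term {endpoint!r}"
                )
    adr_graph = AxisGraph(_ADR_AXIS, terms.keys(), adr_edges)

    aux_axes: dict[str, AxisGraph] = {}
    for axis_id in sorted(edge_table_paths):
        if axis_id == _ADR_AXIS:
            continue
        frame = _read_tsv(edge_table_paths[axis_id], ("child_id", "parent_id"))
        edges = list(zip(frame["child_id"], frame["parent_id"]))
        nodes = {n for edge in edges for n in edge}
        aux_axes[axis_id] = AxisGraph(axis_id, nodes, edges)

    definitions: dict[str, FormalDefinition] = {}
    if definition_table_path is not None:
        def_frame = _read_tsv(definition_table_path, ("term_id", "axis_id", "node_id"))
        for _, row in def_frame.iterrows():
            definitions.setdefault(row["term_id"], FormalDefinition(row["term_id"]))
            definitions[row["term_id"]].axis_bindings[row["axis_id"]] = row["node_id"]

    return Terminology(terms=terms, adr_graph=adr_graph, aux_axes=aux_axes, definitions=definitions)


def write_terminology(terminology: Terminology, out_dir: str | Path) -> dict[str, Path]:
    """Write a terminology to ``out_dir``; returns the emitted paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    terms_path = out_dir / "terms.tsv"
    pd.DataFrame(
        [(t.term_id, t.label, t.level.value) for t in terminology.terms.values()],
        columns=["term_id", "label", "level"],
    ).sort_values("term_id").to_csv(terms_path, sep="\t", index=False)
    paths["terms"] = terms_path

    for axis_id, axis in [(_ADR_AXIS, terminology.adr_graph)] + sorted(
        terminology.aux_axes.items()
    ):
        edge_path = out_dir / f"edges.{axis_id}.tsv"
        pd.DataFrame(
            sorted(axis.isa_edges), columns=["child_id", "parent_id"]
        ).to_csv(edge_path, sep="\t", index=False)
        paths[f"edges.{axis_id}"] = edge_path

    if terminology.definitions:
        rows = [
            (term_id, axis_id, node)
            for term_id in sorted(terminology.definitions)
            for axis_id, node in sorted(terminology.definitions[term_id].axis_bindings.items())
        ]
        def_path = out_dir / "definitions.tsv"
        pd.DataFrame(rows, columns=["term_id", "axis_id", "node_id"]).to_csv(
            def_path, sep="\t", index=False
        )
        paths["definitions"] = def_path
    return paths


def read_lexicon(path: str | Path, source_tag: str = "") -> SynonymLexicon:
    frame = _read_tsv(path, ("word_a", "word_b"))
    return SynonymLexicon.from_pairs(
        zip(frame["word_a"], frame["word_b"]), source_tag=source_tag or str(path)
    )


def write_lexicon(lexicon: SynonymLexicon, path: str | Path) -> None:
    rows = sorted(tuple(sorted(pair)) for pair in lexicon.pairs)
    pd.DataFrame(rows, columns=["word_a", "word_b"]).to_csv(path, sep="\t", index=False)


def read_groupings(path: str | Path) -> list[ReferenceGrouping]:
    frame = _read_tsv(path, ("group_id", "name", "term_id"))
    if frame.empty:
        logger.warning("grouping file %s is empty", path)
        return []
    out = []
    for group_id, sub in frame.groupby("group_id", sort=True):
        names = sub["name"].unique()
        if len(names) > 1:
            raise ValidationError(f"{path}: grouping {group_id!r} has conflicting names {list(names)}")
        out.append(
            ReferenceGrouping(
                group_id=str(group_id), name=names[0], member_term_ids=frozenset(sub["term_id"])
            )
        )
    return out


def write_groupings(groupings: Iterable[ReferenceGrouping], path: str | Path) -> None:
    rows = [
        (g.group_id, g.name, member)
        for g in sorted(groupings, key=lambda g: g.group_id)
        for member in sorted(g.member_term_ids)
    ]
    pd.DataFrame(rows, columns=["group_id", "name", "term_id"]).to_csv(path, sep="\t", index=False)


def read_relations(path: str | Path) -> list[SemanticRelation]:
    frame = _read_tsv(path, ("source", "target", "rel_type", "method_tag"))
    return [
        SemanticRelation.make(
            row["source"], row["target"], RelType(row["rel_type"]), MethodTag(row["method_tag"])
        )
        for _, row in frame.iterrows()
    ]


def write_relations(relations: Iterable[SemanticRelation], path: str | Path) -> None:
    rows = sorted(
        (r.source_term_id, r.target_term_id, r.rel_type.value, r.method_tag.value)
        for r in relations
    )
    pd.DataFrame(rows, columns=["source", "target", "rel_type", "method_tag"]).to_csv(
        path, sep="\t", index=False
    )


def read_clusters(path: str | Path):
    from smqforge.clustering import Cluster, ClusterMethod

    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return [
        Cluster(
            cluster_id=entry["cluster_id"],
            member_term_ids=frozenset(entry["member_ids"]),
            method=ClusterMethod(entry["method"]),
            center_term_id=entry.get("center_term_id"),
            provenance=tuple(entry.get("provenance", ())),
        )
        for entry in payload
    ]


def write_clusters(clusters, path: str | Path) -> None:
    payload = [
        {
            "cluster_id": c.cluster_id,
            "method": c.method.value,
            "member_ids": sorted(c.member_term_ids),
            "center_term_id": c.center_term_id,
            "provenance": list(c.provenance),
        }
        for c in clusters
    ]
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)


def write_matrix(matrix, path: str | Path) -> None:
    """Write a distance/similarity matrix as TSV with id header row/column."""
    frame = pd.DataFrame(matrix.values, index=matrix.term_ids, columns=matrix.term_ids)
    frame.to_csv(path, sep="\t", index_label="term_id")


def read_matrix(path: str | Path, config=None, is_similarity: bool = False):
    from smqforge.distance import DistanceConfig, DistanceMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(
        term_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=float),
        config=config or DistanceConfig(),
        is_similarity=is_similarity,
    )


def write_report(report, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write an evaluation report: TSV with integer percentages, JSON exact."""
    from smqforge.evaluation import percent

    rows = [
        (
            r.group_id,
            r.best_cluster_id,
            r.n_group,
            r.n_cluster,
            r.n_common,
            percent(r.precision),
            percent(r.recall),
            percent(r.f_measure),
        )
        for r in report.records
    ]
    frame = pd.DataFrame(
        rows,
        columns=["group_id", "best_cluster_id", "n_group", "n_cluster", "n_common", "P%", "R%", "F%"],
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "macro_precision": report.macro_precision,
            "macro_recall": report.macro_recall,
            "macro_f": report.macro_f,
            "records": [
                {
                    "group_id": r.group_id,
                    "best_cluster_id": r.best_cluster_id,
                    "n_group": r.n_group,
                    "n_cluster": r.n_cluster,
                    "n_common": r.n_common,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f_measure": r.f_measure,
                    "fallback": r.fallback,
                }
                for r in report.records
            ],
        }
        with open(json_path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
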