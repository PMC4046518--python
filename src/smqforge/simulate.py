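"""Synthetic MedDRA-like terminologies with planted, recoverable structure.

The generator emulates the data regime of the real task without any
licensed resource:

* a four-level term hierarchy (SOC > HLGT > HLT > PT) under a single
  virtual root, organ-system oriented: each SOC is a body region, each HLT
  carries one anatomy concept and its PTs combine that anatomy with
  pathology concepts ("muscle pain", "pain of the muscle", "muscular
  pain");
* two formal-definition axes: ``D`` (abnormality type; one chain of
  configurable depth per pathology concept) and ``B`` (anatomical
  localisation; region > sub-region > anatomy, mirroring the SOC/HLGT/HLT
  skeleton).  Multiword terms bind both axes, single-word terms only D;
* a synonym lexicon covering the pathology and anatomy synonym sets plus
  decoy pairs that occur in no label;
* reference groupings in the SMQ spirit: each grouping collects every PT
  sharing one pathology concept, deliberately spanning several SOCs.

Every string-level regularity the structuring module is supposed to find
(lexical inclusions, insertion/permutation/derivation variants,
compositional synonym pairs) is planted explicitly and recorded in a
:class:`GroundTruth`, so recovery can be scored exactly.  Noise terms that
match no rule are injected by default so precision is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from smqforge import _wordpools as pools
from smqforge.model import (
    AxisGraph,
    FormalDefinition,
    Level,
    ReferenceGrouping,
    RelType,
    SynonymLexicon,
    Term,
    Terminology,
    ValidationError,
)

ROOT_ID = "rt0"


@dataclass
class GeneratorConfig:
    seed: int = 42
    n_soc: int = 6
    n_hlgt_per_soc: int = 4
    n_hlt_per_hlgt: int = 4
    n_pt_per_hlt: int = 13
    anatomy_pool: Sequence[tuple[str, str | None, str | None]] = pools.ANATOMY_POOL
    pathology_pool: Sequence[tuple[str, tuple[str, ...]]] = pools.PATHOLOGY_POOL
    p_of_pattern: float = 0.15
    p_derivation: float = 0.10
    p_variant_pair: float = 0.08
    p_synonym_sibling: float = 0.08
    p_single_grouping: float = 0.75
    p_single_background: float = 0.10
    p_cross_soc_grouping: float = 0.9
    n_groupings: int = 10
    grouping_size_range: tuple[int, int] = (4, 60)
    axis_depth: int = 4
    noise: bool = True

    def __post_init__(self) -> None:
        for name in ("n_soc", "n_hlgt_per_soc", "n_hlt_per_hlgt", "n_pt_per_hlt",
                     "n_groupings", "axis_depth"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be at least 1")
        for name in ("p_of_pattern", "p_derivation", "p_variant_pair", "p_synonym_sibling",
                     "p_single_grouping", "p_single_background", "p_cross_soc_grouping"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        n_hlt = self.n_soc * self.n_hlgt_per_soc * self.n_hlt_per_hlgt
        if n_hlt > len(self.anatomy_pool):
            raise ValidationError(
                f"anatomy pool too small: {n_hlt} HLTs requested, "
                f"{len(self.anatomy_pool)} anatomy concepts available"
            )
        if self.n_soc > len(pools.SOC_REGIONS):
            raise ValidationError("not enough SOC region names")
        if self.n_groupings >= len(self.pathology_pool):
            raise ValidationError("pathology pool must exceed n_groupings")
        n_background = len(self.pathology_pool) - self.n_groupings
        if self.n_pt_per_hlt > n_background:
            raise ValidationError(
                f"n_pt_per_hlt={self.n_pt_per_hlt} exceeds the {n_background} "
                "background pathology concepts"
            )
        lo, hi = self.grouping_size_range
        if not 2 <= lo < hi:
            raise ValidationError("grouping_size_range must satisfy 2 <= lo < hi")
        total_slots = n_hlt * self.n_pt_per_hlt
        if self.n_groupings * max(2, lo) > total_slots:
            raise ValidationError(
                f"{self.n_groupings} groupings of at least {max(2, lo)} terms do not "
                f"fit the {total_slots} PT slots"
            )


@dataclass
class GroundTruth:
    """Planted relations and groupings, for exact recovery scoring."""

    planted_inclusions: set[tuple[str, str]] = field(default_factory=set)
    #: (source, target, rel_type); synonymy endpoints in lexicographic order
    planted_variants: set[tuple[str, str, RelType]] = field(default_factory=set)
    planted_synonyms: set[frozenset[str]] = field(default_factory=set)
    planted_groupings: list[ReferenceGrouping] = field(default_factory=list)
    definition_bindings: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class _PTRecord:
    term_id: str
    label: str
    hlt_id: str
    anatomy: str | None         # anatomy concept (noun), None for noise/singles
    pathology: str              # pathology concept key (D-axis identity)
    surface_path_word: str      # the pathology word appearing in the label
    form: str                   # plain | of | adj | head_sub | exp_sub | double_sub | single | noise
    bind_b: bool


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[Terminology, SynonymLexicon, list[ReferenceGrouping], GroundTruth]:
    """Generate a terminology, lexicon, groupings and their ground truth.

    Deterministic for a fixed config (including the seed).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    anatomy_entries = [config.anatomy_pool[i] for i in rng.permutation(len(config.anatomy_pool))]
    pathology_entries = [
        config.pathology_pool[i] for i in rng.permutation(len(config.pathology_pool))
    ]
    grouping_concepts = [p for p, _ in pathology_entries[: config.n_groupings]]
    background_concepts = [p for p, _ in pathology_entries[config.n_groupings:]]
    synonyms = {p: list(syns) for p, syns in pathology_entries}
    anatomy_info = {noun: (adj, syn) for noun, adj, syn in anatomy_entries}

    # --- skeleton: SOC / HLGT / HLT terms and the mirrored B axis ---------
    terms: dict[str, Term] = {ROOT_ID: Term(ROOT_ID, "terminology root", Level.OTHER)}
    adr_edges: list[tuple[str, str]] = []
    b_edges: list[tuple[str, str]] = []
    hlt_ids: list[str] = []
    hlt_anatomy: dict[str, str] = {}
    hlt_soc: dict[str, str] = {}
    anatomy_cursor = 0
    for i in range(config.n_soc):
        region = pools.SOC_REGIONS[i]
        soc_id = f"soc{i}"
        terms[soc_id] = Term(soc_id, f"{region} disorders", Level.SOC)
        adr_edges.append((soc_id, ROOT_ID))
        b_edges.append((f"B:{region}", "B:body"))
        for j in range(config.n_hlgt_per_soc):
            hlgt_id = f"hg{i}_{j}"
            terms[hlgt_id] = Term(hlgt_id, f"{region} disorders group {j + 1}", Level.HLGT)
            adr_edges.append((hlgt_id, soc_id))
            b_edges.append((f"B:{region}/{j}", f"B:{region}"))
            for k in range(config.n_hlt_per_hlgt):
                anatomy = anatomy_entries[anatomy_cursor][0]
                anatomy_cursor += 1
                hlt_id = f"ht{i}_{j}_{k}"
                terms[hlt_id] = Term(hlt_id, f"{anatomy} disorders", Level.HLT)
                adr_edges.append((hlt_id, hlgt_id))
                b_edges.append((f"B:{anatomy}", f"B:{region}/{j}"))
                hlt_ids.append(hlt_id)
                hlt_anatomy[hlt_id] = anatomy
                hlt_soc[hlt_id] = soc_id

    # --- assign pathology concepts to HLT slots ---------------------------
    capacity = {h: config.n_pt_per_hlt for h in hlt_ids}
    uses: dict[str, list[tuple[str, str]]] = {h: [] for h in hlt_ids}  # hlt -> [(pathology, kind)]
    lo, hi = config.grouping_size_range
    total_slots = len(hlt_ids) * config.n_pt_per_hlt
    min_uses = max(2, lo)
    # cap at a fair share of the slot capacity so allocation never exhausts
    max_uses = max(min_uses, min((hi - 1) // 3, total_slots // config.n_groupings))
    soc_hlts: dict[str, list[str]] = {}
    for h in hlt_ids:
        soc_hlts.setdefault(hlt_soc[h], []).append(h)

    grouping_is_cross: dict[str, bool] = {}
    for g_index, concept in enumerate(grouping_concepts):
        cross = config.p_cross_soc_grouping > 0 and (
            g_index == 0 or rng.random() < config.p_cross_soc_grouping
        )
        cross = cross and config.n_soc >= 2
        n_uses = int(rng.integers(min_uses, max_uses + 1))
        soc_ids = sorted(soc_hlts)
        if cross:
            n_socs = int(rng.integers(2, min(4, config.n_soc) + 1))
            chosen_socs = [soc_ids[x] for x in rng.choice(len(soc_ids), n_socs, replace=False)]
        else:
            chosen_socs = [soc_ids[int(rng.integers(len(soc_ids)))]]
        candidates = [h for s in chosen_socs for h in soc_hlts[s] if capacity[h] > 0]
        if len(candidates) < n_uses:
            candidates = [h for h in hlt_ids if capacity[h] > 0]
        n_uses = min(n_uses, len(candidates))
        chosen = [candidates[x] for x in rng.choice(len(candidates), n_uses, replace=False)]
        if cross and len({hlt_soc[h] for h in chosen}) < 2:
            # force a second SOC so the cross-SOC property holds by construction
            other = [h for h in hlt_ids if capacity[h] > 0 and hlt_soc[h] != hlt_soc[chosen[0]]]
            chosen[-1] = other[int(rng.integers(len(other)))]
        grouping_is_cross[concept] = len({hlt_soc[h] for h in chosen}) >= 2
        for h in chosen:
            uses[h].append((concept, "grouping"))
            capacity[h] -= 1

    for h in hlt_ids:
        n_fill = capacity[h]
        picked = [background_concepts[x]
                  for x in rng.choice(len(background_concepts), n_fill, replace=False)]
        for concept in picked:
            uses[h].append((concept, "background"))
        capacity[h] = 0

    # --- emit PT records --------------------------------------------------
    records: list[_PTRecord] = []
    counter = 0

    def new_pt(label: str, hlt_id: str, anatomy: str | None, pathology: str,
               surface: str, form: str, bind_b: bool) -> _PTRecord:
        nonlocal counter
        record = _PTRecord(f"pt{counter:05d}", label, hlt_id, anatomy, pathology,
                           surface, form, bind_b)
        counter += 1
        records.append(record)
        return record

    concept_first_hlt: dict[str, str] = {}
    combo_forms: list[tuple[list[_PTRecord], str, str]] = []  # (forms, anatomy, pathology)
    for hlt_id in hlt_ids:
        anatomy = hlt_anatomy[hlt_id]
        adjective, anat_syn = anatomy_info[anatomy]
        for concept, _kind in uses[hlt_id]:
            concept_first_hlt.setdefault(concept, hlt_id)
            draw = rng.random()
            if draw < config.p_of_pattern:
                primary = "of"
            elif adjective is not None and draw < config.p_of_pattern + config.p_derivation:
                primary = "adj"
            else:
                primary = "plain"

            alternate = None
            if rng.random() < config.p_variant_pair:
                if primary == "plain":
                    if adjective is not None and rng.random() < 0.5:
                        alternate = "adj"
                    else:
                        alternate = "of"
                else:
                    alternate = "plain"

            def render(form: str) -> str:
                if form == "plain":
                    return f"{anatomy} {concept}"
                if form == "of":
                    return f"{concept} of the {anatomy}"
                return f"{adjective} {concept}"

            emitted = [new_pt(render(primary), hlt_id, anatomy, concept, concept, primary, True)]
            if alternate is not None:
                emitted.append(
                    new_pt(render(alternate), hlt_id, anatomy, concept, concept, alternate, True)
                )
            plain_record = next((r for r in emitted if r.form == "plain"), None)

            if plain_record is not None and rng.random() < config.p_synonym_sibling:
                draw = rng.random()
                kind = "head_sub"
                if anat_syn is not None and draw >= 0.6:
                    kind = "exp_sub" if draw < 0.85 else "double_sub"
                p_syn = synonyms[concept][int(rng.integers(len(synonyms[concept])))]
                if kind == "head_sub":
                    label = f"{anatomy} {p_syn}"
                    surface = p_syn
                elif kind == "exp_sub":
                    label = f"{anat_syn} {concept}"
                    surface = concept
                else:
                    label = f"{anat_syn} {p_syn}"
                    surface = p_syn
                emitted.append(new_pt(label, hlt_id, anatomy, concept, surface, kind, True))
            combo_forms.append((emitted, anatomy, concept))

    # single-word PTs (the general terms lexical inclusion points at)
    single_word_pt: dict[str, str] = {}
    for concept in grouping_concepts + background_concepts:
        if concept not in concept_first_hlt:
            continue
        p_emit = (config.p_single_grouping if concept in grouping_concepts
                  else config.p_single_background)
        if rng.random() < p_emit:
            record = new_pt(concept, concept_first_hlt[concept], None, concept,
                            concept, "single", False)
            single_word_pt[concept] = record.term_id

    # noise terms: match no structuring rule
    if config.noise:
        for word in pools.NOISE_SINGLE_WORDS:
            hlt_id = hlt_ids[int(rng.integers(len(hlt_ids)))]
            new_pt(word, hlt_id, None, f"noise:{word}", word, "noise", False)
        for head in pools.NOISE_HEADS:
            for modifier in pools.NOISE_MODIFIERS:
                hlt_id = hlt_ids[int(rng.integers(len(hlt_ids)))]
                new_pt(f"{modifier} {head}", hlt_id, None, f"noise:{head}", head,
                       "noise", False)

    labels = [r.label for r in records]
    if len(set(labels)) != len(labels):
        duplicates = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate generated labels: {duplicates[:5]}")

    # --- terminology assembly ---------------------------------------------
    for record in records:
        terms[record.term_id] = Term(record.term_id, record.label, Level.PT)
        adr_edges.append((record.term_id, record.hlt_id))
    adr_graph = AxisGraph("ADR", terms.keys(), adr_edges)

    d_edges: list[tuple[str, str]] = []
    for concept in sorted({r.pathology for r in records}):
        chain = [f"D:{concept}:{i}" for i in range(1, config.axis_depth)] + [f"D:{concept}"]
        previous = "D:root"
        for node in chain:
            d_edges.append((node, previous))
            previous = node
    d_axis = AxisGraph("D", {n for e in d_edges for n in e}, d_edges)
    b_axis = AxisGraph("B", {n for e in b_edges for n in e}, b_edges)

    definitions: dict[str, FormalDefinition] = {}
    for record in records:
        bindings = {"D": f"D:{record.pathology}"}
        if record.bind_b and record.anatomy is not None:
            bindings["B"] = f"B:{record.anatomy}"
        definitions[record.term_id] = FormalDefinition(record.term_id, bindings)

    terminology = Terminology(
        terms=terms, adr_graph=adr_graph, aux_axes={"D": d_axis, "B": b_axis},
        definitions=definitions,
    )

    # --- lexicon ----------------------------------------------------------
    lexicon_pairs: list[tuple[str, str]] = list(pools.DECOY_SYNONYM_PAIRS)
    for concept, syns in sorted(synonyms.items()):
        lexicon_pairs += [(concept, syn) for syn in syns]
    for noun, (adj, syn) in sorted(anatomy_info.items()):
        if syn is not None:
            lexicon_pairs.append((noun, syn))
    lexicon = SynonymLexicon.from_pairs(lexicon_pairs, source_tag="synthetic-lexicon")

    # --- groupings --------------------------------------------------------
    groupings: list[ReferenceGrouping] = []
    for g_index, concept in enumerate(sorted(grouping_concepts)):
        members = frozenset(r.term_id for r in records if r.pathology == concept)
        grouping = ReferenceGrouping(f"smq{g_index:03d}", f"{concept} (topic)", members)
        if not lo <= len(members) <= hi:
            raise ValidationError(
                f"grouping {concept!r} has {len(members)} members, outside {lo}..{hi}"
            )
        groupings.append(grouping)
    if config.p_cross_soc_grouping > 0 and config.n_groupings >= 2 and config.n_soc >= 2:
        assert any(grouping_is_cross.values()), "no cross-SOC grouping generated"

    # --- ground truth -----------------------------------------------------
    truth = GroundTruth(planted_groupings=groupings)
    truth.definition_bindings = {
        t: dict(d.axis_bindings) for t, d in definitions.items()
    }
    for record in records:
        if record.form in ("single", "noise"):
            continue
        parent = single_word_pt.get(record.surface_path_word)
        if parent is not None and parent != record.term_id:
            truth.planted_inclusions.add((record.term_id, parent))
            truth.planted_variants.add((record.term_id, parent, RelType.HIERARCHICAL))
    for emitted, _anatomy, _concept in combo_forms:
        primary_like = [r for r in emitted if r.form in ("plain", "of", "adj")]
        for i, a in enumerate(primary_like):
            for b in primary_like[i + 1:]:
                x, y = sorted((a.term_id, b.term_id))
                truth.planted_variants.add((x, y, RelType.SYNONYMY))
        plain = next((r for r in emitted if r.form == "plain"), None)
        if plain is not None:
            for sibling in emitted:
                if sibling.form in ("head_sub", "exp_sub", "double_sub"):
                    truth.planted_synonyms.add(frozenset((plain.term_id, sibling.term_id)))
    return terminology, lexicon, groupings, truth


def write_outputs(
    terminology: Terminology,
    lexicon: SynonymLexicon,
    groupings: Sequence[ReferenceGrouping],
    out_dir,
) -> dict:
    """Write the full generated file set via the interchange writers."""
    from pathlib import Path

    from smqforge import io as sfio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sfio.write_terminology(terminology, out_dir)
    sfio.write_lexicon(lexicon, out_dir / "lexicon.tsv")
    paths["lexicon"] = out_dir / "lexicon.tsv"
    sfio.write_groupings(groupings, out_dir / "groupings.tsv")
    paths["groupings"] = out_dir / "groupings.tsv"
    return paths
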