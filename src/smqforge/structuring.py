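"""Terminology structuring: inducing relations from term strings alone.

Short medical noun phrases are decomposed into a *head* (the governing
noun span) and an *expansion* (the modifier span).  English medical terms
are right-headed ("muscle pain" -> head "pain") except for the
of-construction ("coarctation of the aorta" -> head "coarctation").  From
the decomposition three families of relations are induced over the flat
PT vocabulary:

* **lexical inclusion** — a term whose head span is itself a vocabulary
  term is a hierarchical child of that term ("muscle pain" is-a "pain");
  only head-based relations are induced, never expansion-based
  (associative) ones, and both endpoints must be vocabulary terms;
* **morpho-syntactic variants** — insertion (hierarchical: the longer
  term is more specific), permutation (synonymy) and morphological
  derivation via a suffix-rewrite table (synonymy); when several rules
  fire on one pair the hierarchical reading prevails;
* **compositional synonymy** — substituting lexicon-attested synonyms on
  the head, the expansion, or both yields a synonym whenever the rewritten
  label is itself a vocabulary term ("muscle pain" ~ "muscle ache" given
  {pain, ache}).

No external tagger or parser is used: the decomposition relies on a closed
stopword list and right-headedness, which covers short noun-phrase
vocabularies of the MedDRA kind.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from smqforge.model import (
    MethodTag,
    RelType,
    SemanticRelation,
    SynonymLexicon,
    Terminology,
    ValidationError,
    normalize_label,
)

#: closed-class words never part of a head or expansion content span
STOPWORDS = frozenset({"of", "the", "a", "an", "and", "or", "in", "on", "to", "with", "due"})

#: default adjective -> noun suffix rewrites (invertible string rules)
DEFAULT_DERIVATION_RULES: tuple[tuple[str, str], ...] = (
    ("ial", "y"),    # arterial / artery
    ("inal", "en"),  # abdominal / abdomen
    ("ular", "le"),  # muscular / muscle, ventricular / ventricle
    ("ical", "ex"),  # cortical / cortex
    ("al", "um"),    # sternal / sternum, rectal / rectum
    ("ic", "us"),    # thymic / thymus
    ("al", ""),      # orbital / orbit, ductal / duct
)


class Pattern(str, Enum):
    PLAIN_NP = "PLAIN_NP"
    OF_NP = "OF_NP"
    SINGLE_WORD = "SINGLE_WORD"


@dataclass(frozen=True)
class SyntacticAnalysis:
    """Head/expansion decomposition of one term label."""

    term_id: str
    tokens: tuple[str, ...]
    head: tuple[str, ...]
    expansion: tuple[str, ...]
    pattern: Pattern

    @property
    def head_label(self) -> str:
        return " ".join(self.head)

    @property
    def expansion_label(self) -> str:
        return " ".join(self.expansion)


class DerivationTable:
    """Suffix-rewrite rules relating adjectives to their noun bases.

    Each rule maps an adjectival suffix to the noun suffix it replaces;
    two tokens are derivationally related when their possible base forms
    intersect ("arterial" -> base "artery" -> matches "artery").
    """

    def __init__(self, rules: Iterable[tuple[str, str]] = DEFAULT_DERIVATION_RULES,
                 min_stem: int = 3):
        self.rules = tuple(rules)
        self.min_stem = min_stem

    def bases(self, token: str) -> frozenset[str]:
        """The token itself plus every base form a rule can produce."""
        out = {token}
        for adj_suffix, noun_suffix in self.rules:
            if token.endswith(adj_suffix) and len(token) - len(adj_suffix) >= self.min_stem:
                out.add(token[: -len(adj_suffix)] + noun_suffix)
        return frozenset(out)

    def canonical(self, token: str, attested: frozenset[str] | set[str]) -> str:
        """Rewrite ``token`` to its noun base when that base is attested.

        Rules are tried in declaration order; the first rewrite producing a
        token that actually occurs in the vocabulary wins.  Unattested
        rewrites are discarded, which keeps the rewriting precise on real
        word lists.
        """
        for adj_suffix, noun_suffix in self.rules:
            if token.endswith(adj_suffix) and len(token) - len(adj_suffix) >= self.min_stem:
                base = token[: -len(adj_suffix)] + noun_suffix
                if base != token and base in attested:
                    return base
        return token

    def related(self, a: str, b: str) -> bool:
        return a != b and bool(self.bases(a) & self.bases(b))


def parse_term(label: str, term_id: str = "") -> SyntacticAnalysis:
    """Decompose a term label into head and expansion components.

    ``X of (the) Y`` terms take ``X`` as head and ``Y`` as expansion; other
    multiword terms are right-headed with the maximal head (all tokens but
    the leftmost modifier); single words are their own head.
    """
    tokens = tuple(normalize_label(label).split())
    if not tokens:
        raise ValidationError("cannot parse an empty label")
    if len(tokens) == 1:
        return SyntacticAnalysis(term_id, tokens, tokens, (), Pattern.SINGLE_WORD)
    if "of" in tokens:
        pivot = tokens.index("of")
        head = tokens[:pivot]
        expansion = tuple(t for t in tokens[pivot + 1:] if t not in STOPWORDS)
        if head and expansion:
            return SyntacticAnalysis(term_id, tokens, head, expansion, Pattern.OF_NP)
    content = tuple(t for t in tokens if t not in STOPWORDS)
    if len(content) == 1:
        return SyntacticAnalysis(term_id, tokens, content, (), Pattern.SINGLE_WORD)
    return SyntacticAnalysis(term_id, tokens, content[1:], content[:1], Pattern.PLAIN_NP)


def analyze_terms(terminology: Terminology) -> list[SyntacticAnalysis]:
    """Parse every PT-level term of the terminology."""
    return [
        parse_term(terminology.terms[t].label, term_id=t) for t in terminology.pt_ids()
    ]


def _vocabulary(terminology_or_vocab) -> dict[str, str]:
    """Accept a Terminology or a prebuilt normalised-label -> id mapping."""
    if isinstance(terminology_or_vocab, Terminology):
        return terminology_or_vocab.label_index()
    return dict(terminology_or_vocab)


def induce_lexical_inclusions(
    analyses: Sequence[SyntacticAnalysis], vocabulary: Mapping[str, str] | Terminology
) -> list[SemanticRelation]:
    """Hierarchical relations from head-span inclusion.

    The maximal head is preferred; when its label is not a vocabulary term
    successively shorter right-anchored head spans are tried.  At most one
    parent is emitted per term.
    """
    vocab = _vocabulary(vocabulary)
    relations = []
    for analysis in analyses:
        if analysis.pattern is Pattern.SINGLE_WORD:
            continue
        if analysis.pattern is Pattern.OF_NP:
            candidates = [analysis.head]
        else:
            head = analysis.head
            candidates = [head[i:] for i in range(len(head))]
        for span in candidates:
            parent = vocab.get(" ".join(span))
            if parent is not None and parent != analysis.term_id:
                relations.append(
                    SemanticRelation.make(
                        analysis.term_id, parent, RelType.HIERARCHICAL, MethodTag.LEX_INCLUSION
                    )
                )
                break
    return relations


def _content(analysis: SyntacticAnalysis) -> tuple[str, ...]:
    return tuple(t for t in analysis.tokens if t not in STOPWORDS)


def induce_variants(
    analyses: Sequence[SyntacticAnalysis],
    vocabulary: Mapping[str, str] | Terminology,
    derivation_table: DerivationTable | None = None,
) -> list[SemanticRelation]:
    """Pairwise morpho-syntactic variant relations.

    Content tokens are first normalised through the derivation table; then
    for a pair of terms:

    * equal normalised token sequences, different raw labels -> DERIVATION
      synonymy;
    * equal normalised multisets, different order -> PERMUTATION synonymy;
    * one multiset strictly contained in the other -> INSERTION (possibly
      combined with permutation/derivation): hierarchical, the longer term
      being the more specific child.

    Candidate pairs are restricted to terms sharing at least one
    content-token base, which keeps the scan near-linear on real
    vocabularies.
    """
    table = derivation_table or DerivationTable()
    vocab = _vocabulary(vocabulary)
    known = {a.term_id for a in analyses} | set(vocab.values())

    attested = frozenset(t for a in analyses for t in _content(a))
    prepared = []
    for analysis in analyses:
        content = _content(analysis)
        canon = tuple(table.canonical(t, attested) for t in content)
        prepared.append((analysis, content, canon, Counter(canon)))

    buckets: dict[str, list[int]] = defaultdict(list)
    for i, (_, _, canon, _) in enumerate(prepared):
        for base in set(canon):
            buckets[base].append(i)

    seen_pairs: set[tuple[int, int]] = set()
    relations: dict[tuple[str, str], SemanticRelation] = {}
    for bucket in buckets.values():
        for i, j in itertools.combinations(bucket, 2):
            if (i, j) in seen_pairs:
                continue
            seen_pairs.add((i, j))
            a_analysis, a_content, a_canon, a_counts = prepared[i]
            b_analysis, b_content, b_canon, b_counts = prepared[j]
            if a_analysis.term_id not in known or b_analysis.term_id not in known:
                continue
            rel = None
            if a_counts == b_counts:
                if a_content == b_content:
                    continue  # same content sequence (stopword variation only)
                if a_canon == b_canon:
                    rel_type = RelType.SYNONYMY  # derivation
                else:
                    rel_type = RelType.SYNONYMY  # permutation
                rel = SemanticRelation.make(
                    a_analysis.term_id, b_analysis.term_id, rel_type, MethodTag.VARIANT
                )
            elif a_counts - b_counts == Counter():  # a strictly contained in b
                rel = SemanticRelation.make(
                    b_analysis.term_id, a_analysis.term_id, RelType.HIERARCHICAL, MethodTag.VARIANT
                )
            elif b_counts - a_counts == Counter():
                rel = SemanticRelation.make(
                    a_analysis.term_id, b_analysis.term_id, RelType.HIERARCHICAL, MethodTag.VARIANT
                )
            if rel is not None:
                key = tuple(sorted((rel.source_term_id, rel.target_term_id)))
                previous = relations.get(key)
                # hierarchical prevails over synonymy on the same pair
                if previous is None or (
                    previous.rel_type is RelType.SYNONYMY
                    and rel.rel_type is RelType.HIERARCHICAL
                ):
                    relations[key] = rel
    return sorted(
        relations.values(), key=lambda r: (r.source_term_id, r.target_term_id, r.rel_type.value)
    )


def lexicon_synonyms(
    vocabulary: Mapping[str, str] | Terminology, lexicon: SynonymLexicon
) -> list[SemanticRelation]:
    """Synonymy between two single-word vocabulary terms attested by the lexicon."""
    vocab = _vocabulary(vocabulary)
    single = {label: tid for label, tid in vocab.items() if " " not in label}
    relations = []
    for pair in lexicon.pairs:
        a, b = sorted(pair)
        if a in single and b in single and single[a] != single[b]:
            relations.append(
                SemanticRelation.make(single[a], single[b], RelType.SYNONYMY, MethodTag.LEXICON)
            )
    return sorted(relations, key=lambda r: (r.source_term_id, r.target_term_id))


def compositional_synonyms(
    analyses: Sequence[SyntacticAnalysis],
    vocabulary: Mapping[str, str] | Terminology,
    lexicon: SynonymLexicon,
) -> list[SemanticRelation]:
    """Synonymy between complex terms via component substitution.

    For each multiword term, lexicon synonyms are substituted on the head
    component, on the expansion component, and on both; a relation is
    emitted whenever the rewritten label is itself a vocabulary term.  The
    untouched component is left identical by construction.
    """
    vocab = _vocabulary(vocabulary)
    syn_map = lexicon.synonym_map()
    relations: set[SemanticRelation] = set()
    for analysis in analyses:
        if analysis.pattern is Pattern.SINGLE_WORD:
            continue
        head_options = syn_map.get(analysis.head_label, set())
        exp_options = syn_map.get(analysis.expansion_label, set())
        rewrites = []
        rewrites += [(h, analysis.expansion_label) for h in head_options]
        rewrites += [(analysis.head_label, e) for e in exp_options]
        rewrites += [(h, e) for h in head_options for e in exp_options]
        for head, expansion in rewrites:
            label = _rebuild_label(analysis, head, expansion)
            other = vocab.get(label)
            if other is not None and other != analysis.term_id:
                relations.add(
                    SemanticRelation.make(
                        analysis.term_id, other, RelType.SYNONYMY, MethodTag.COMPOSITIONAL
                    )
                )
    return sorted(relations, key=lambda r: (r.source_term_id, r.target_term_id))


def _rebuild_label(analysis: SyntacticAnalysis, head: str, expansion: str) -> str:
    """Reinsert rewritten components into the term's surface template."""
    if analysis.pattern is Pattern.OF_NP:
        pivot = analysis.tokens.index("of")
        middle = " ".join(analysis.tokens[pivot : len(analysis.tokens) - len(analysis.expansion)])
        return f"{head} {middle} {expansion}"
    return f"{expansion} {head}"


def structure_terminology(
    terminology: Terminology,
    lexicons: Sequence[SynonymLexicon] = (),
    derivation_table: DerivationTable | None = None,
) -> list[SemanticRelation]:
    """Run all structuring methods over the PT vocabulary; deduplicated union."""
    analyses = analyze_terms(terminology)
    vocab = terminology.label_index()
    relations: set[SemanticRelation] = set()
    relations.update(induce_lexical_inclusions(analyses, vocab))
    relations.update(induce_variants(analyses, vocab, derivation_table))
    for lexicon in lexicons:
        relations.update(lexicon_synonyms(vocab, lexicon))
        relations.update(compositional_synonyms(analyses, vocab, lexicon))
    return sorted(
        relations,
        key=lambda r: (r.source_term_id, r.target_term_id, r.rel_type.value, r.method_tag.value),
    )
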