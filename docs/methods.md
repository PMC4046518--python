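# Methods

## Data model

A terminology is a set of levelled terms (SOC, HLGT, HLT, PT, LLT, OTHER)
with is-a edges stored child → parent. All hierarchies are DAGs: multiple
parents are allowed everywhere, because SNOMED-aligned resources are not
trees. Only PT-level terms are processed by the methods — they are the coding
and grouping unit in pharmacovigilance practice; LLTs are representable but
inert. Labels are matched case-insensitively after whitespace normalisation;
identifiers are opaque strings.

Formal definitions bind a term to nodes of auxiliary axes — `D` (abnormality
type) and `B` (anatomical localisation) by convention, extensible — each
axis carrying its own is-a DAG. Axes other than the term (ADR) hierarchy are
optional per term: real alignment resources cover only part of a vocabulary,
so partial bindings are the normal case, not an error.

## Semantic distance

`sp(a, b)` is the minimum number of is-a edges connecting two nodes,
traversed in either direction (through common ancestors or descendants),
every edge weighing 1. Disconnected pairs yield an infinite sentinel under
the default policy (clustering then treats them as beyond any threshold);
the `FAIL` policy raises instead.

* **Rada**: `sp` itself.
* **Leacock–Chodorow**: `−log_b((sp + 1) / (2 · max_depth))`, a similarity.
  The node-count convention `sp + 1` keeps the value finite at `sp = 0`
  (identical terms score the maximum `log_b(2 · max_depth)`). `max_depth` is
  recomputed per loaded axis as the longest root-to-node path. The log base
  defaults to 2: the conventional radius threshold 4.10 for this measure
  exceeds the natural-log maximum for plausible hierarchy depths (≤ 14
  levels ⇒ ln 28 ≈ 3.33 < 4.10 < log₂ 28 ≈ 4.81), so base 2 is the reading
  under which that threshold is attainable; the base is configurable.
* **Zhong**: each node carries a milestone `m(n) = 1 / (2 · k^depth(n))`
  (`k = 2` by default, the original formulation); the distance is
  `(m(ccp) − m(a)) + (m(ccp) − m(b))` minimised over common ancestors, which
  selects the deepest common parent (ties broken by node id for
  determinism). In a DAG, `depth` is the *longest* root-to-node path — the
  one depth notion monotone along ancestry, which keeps milestone
  differences non-negative. Values lie in [0, 1) for k ≥ 2.

The combined value is the weighted mean over enabled axes,
`Σ W_i · sd_i / Σ W_j`, with default weights ADR = 1, D = 2, B = 1 (the
abnormality type dominates the clinical identity of a reaction term). When a
term lacks a binding on an axis, that axis is dropped for the pair and the
weights renormalise over the remaining axes (policy `RENORMALIZE`; `FAIL`
raises). With formal definitions disabled the combination reduces exactly to
the raw measure on the term hierarchy. Matrices are exactly symmetrised
(`(M + Mᵀ)/2`) to remove floating-point asymmetry; distance diagonals are 0,
similarity diagonals are the per-term self-similarity maximum.

## Terminology structuring

No external tagger or parser is used: MedDRA-like PTs are short English
noun phrases, and a closed stopword list plus two patterns cover them —
`X of (the) Y` takes `X` as head and `Y` as expansion; other multiword terms
are right-headed with the *maximal* head (all content tokens but the
leftmost modifier). When the maximal head is not itself a vocabulary label,
successively shorter right-anchored spans are tried, so
`anticonvulsant drug level` attaches to `drug level` when present and to
`level` otherwise.

* **Lexical inclusion** emits child → parent hierarchy from term to head
  term; expansion-based (associative) relations are never emitted, and both
  endpoints must be PT labels.
* **Variants** are detected pairwise after rewriting tokens through a
  derivation table of suffix rules (e.g. `-ial`↔`-y`, `-ular`↔`-le`,
  `-al`↔`-um`); a rewrite is applied only when the produced base form is
  attested among the vocabulary's tokens, which keeps the rewriting precise.
  Equal token multisets with different sequences are permutation/derivation
  synonyms; strict multiset containment is an insertion — hierarchical,
  longer term as child — and prevails when rules combine. Candidate pairs
  are bucketed by shared token base, keeping the scan near-linear; the
  brute-force pairwise scan remains the semantics being approximated and the
  bucketing is exact for the implemented rules (every rule requires a shared
  base).
* **Compositional synonymy** substitutes lexicon-attested synonyms on the
  head span, the expansion span, or both, and emits a synonym whenever the
  rewritten label is a vocabulary term. "Simple terms" for direct lexicon
  synonymy are single-word terms.

Induced hierarchies are acyclic by construction: inclusion strictly reduces
token count and insertion strictly increases it, so the edge relation is
well-founded.

## Clustering and merging

Radius clustering treats every term as a candidate centre
(`{t : d(c, t) ≤ θ}`, or `sim ≥ θ` for similarities); duplicate member sets
are kept once and clusters below the minimum size (2 for matrix methods)
are dropped. Agglomerative clustering cuts the dendrogram into
`min(k, n)` disjoint clusters; the linkage is configurable and defaults to
average (the classical description names no linkage); similarities convert
as `max_sim − sim`, and infinite distances are replaced by a value beyond
the largest finite one so unreachable pairs merge last. Graph clustering
orients hierarchical relations parent → child and emits the
forward-reachable set of every source vertex (per-vertex seeding is
available for sensitivity analysis), then closes each cluster under
synonymy edges.

Merging unions any pair of clusters with `|A∩B| / min(|A|,|B|) ≥ 0.8`,
iterated to a fixed point — the min-denominator makes the rule also absorb
strict subset inclusions, which is the reading under which the "smaller
cluster included in larger" step needs no separate mechanism. Pairs are
processed by descending overlap with id tie-breaks, so the fixed point is
deterministic; `merge_within` is idempotent. The comparison is inclusive
(exactly 80% merges). The same rule merges across the two strategies'
outputs.

## Evaluation

Precision = common / cluster size, recall = common / grouping size, F =
harmonic mean (0 when both are 0). Each cluster is assigned to its maximal-F
grouping, ties resolved by larger overlap then smaller group id; each
grouping reports its best assigned cluster, falling back (flagged) to the
globally best cluster when nothing was assigned, so both readings of the
assignment protocol are reproducible. Macro averages are unweighted means
over all groupings including zero records. The baseline builds one cluster
per HLT from its direct PT children. Printed percentages round half away
from zero; exact fractions are always emitted alongside.

Cross-validation partitions the *groupings* (not the terms) into ten seeded
folds; each fold's single tuning subset selects the grid value with the best
macro-F, and the modal winner across folds is retained, ties to the smaller
threshold. Because a smaller radius can tie a larger one on easy folds, the
protocol may prefer the smaller value even when a larger radius is globally
best — this is a property of the protocol, preserved deliberately.

## Synthetic benchmark

The generator emulates the study conditions: a 4-level hierarchy under a
virtual root (6 SOCs × 4 HLGTs × 4 HLTs × 13 PT slots ⇒ ≈ 1,500 PTs at the
default seed 42), organ-system oriented — each HLT carries one anatomy
concept, each PT one (anatomy, pathology) pair rendered as `"<anatomy>
<pathology>"`, `"<pathology> of the <anatomy>"` (p = 0.15) or a derived
adjectival form (p = 0.10). Word pools ship in the repository (~100 anatomy
nouns, 18 with rule-regular adjectives and 12 with synonyms; 50 pathology
concepts with 1–2 synonyms each). Variant pairs (p = 0.08) and
synonym-substituted siblings (p = 0.08; head, expansion or double
substitution) are planted alongside; the general single-word term that
lexical inclusion points at is emitted for 75% of grouping topics and 10% of
background pathologies. Noise (on by default) adds 40 terms that match no
structuring rule, and the lexicon carries decoy pairs occurring in no label,
so precision is exercised, not only recall.

The `D` axis gives every pathology concept its own root chain of depth 4;
the `B` axis mirrors the SOC/HLGT/HLT skeleton at depth 3. Groupings are
pathology topics — every PT sharing one pathology concept — and span ≥ 2
SOCs with probability 0.9 (at least one cross-SOC grouping is forced
whenever the probability is positive). Under the default weights this
geometry places within-topic pairs at combined Rada distance ≤ 3.5 and
cross-topic pairs at ≥ 4.5, so the conventional radius 4 separates topics
exactly — the benchmark rewards the published threshold rather than being
tuned to it after the fact. Multiword terms bind both axes; single-word and
noise terms bind only `D`, exercising the renormalisation path.

What passing on this benchmark does *not* show: real MedDRA labels are
longer, noisier and less compositional; real alignment resources cover only
about half the vocabulary; real SMQs mix semantic criteria beyond a shared
abnormality. Recovery rates here are upper bounds tied to the planted
generative process, not estimates of performance on licensed data — the
published averages on real data are far below the synthetic ones for
exactly these reasons.

## Numerical choices and limitations

* Distances are exact small-integer or dyadic-rational arithmetic in most
  paths; comparisons in tests use standard relative tolerances.
* Disconnected-pair sentinels are `inf` (distance) / `−inf` (similarity);
  they survive matrix assembly and are handled by each consumer.
* Deduplication of radius clusters counts distinct member sets (not
  distinct centres); the lexicographically smallest centre is kept.
* HAC at n = 1 returns the singleton without calling the linkage routine.
* The variant rule inventory is insertion, permutation and derivation;
  richer transformation grammars (multi-word derivation, coordination) are
  out of scope, as is corpus-context-based structuring.
* The fixed-point merge is quadratic per pass in the number of clusters;
  it is intended for the post-deduplication cluster counts (hundreds), not
  for raw per-centre sets.
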