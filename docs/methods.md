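# Methods

This note documents the models, file contracts, calibrated constants and
design choices behind `upkmine`, and what the synthetic-data experiments do
and do not demonstrate.

## Relation model

A relation is a five-field record: **substance** (required), **effect type**
(`Increase` or `Reduction`), **process**, **disease**, **body part** (each
optional, but at least one of process/disease must be present — an effect
must act *on* something). Absent fields render as `N/A` in TSV output.
Relation identity, used for deduplication, novelty checking and evaluation,
is the five-field tuple after whitespace normalization and case folding; no
synonym resolution is attempted.

The effect lexicon ships with five connector verbs (induce, contribute,
increase → Increase; reduce, resistant → Reduction) and is extensible via a
two-column TSV. Words are Porter-stemmed at load time and all matching is
stem-based, so inflected forms ("induces", "inducer", "induced") hit the
same entry. The stemmer is the classic Porter (1980) algorithm implemented
in `upkmine.stemming` and validated against the algorithm's published
example vocabulary.

## Parse graphs and path rules

Sentences are represented as graphs: tokens as vertices, typed links as
edges, stored with `left < right` so that a rule's `+`/`−` sign can be
resolved positionally at traversal time ("search right" / "search left").
Link labels are kept in *reduced* form — the leading uppercase primary type,
subscripts stripped (`Ss` → `S`, `MVp` → `MV`) — because extraction should
generalize over singular/plural and similar subscript distinctions.

Rather than embedding a syntactic parser, the package defines a line-based
interchange format (one block per sentence: `S` header, `W` token lines,
`L` link lines, optional `E` effect and `T` concept-tag lines for training
blocks). Any parser can be adapted to emit it. The bundled *toy linker*
instantiates graphs only for a fixed set of template sentence shapes and
refuses anything else; it is test scaffolding, not a parser.

**Rule learning.** Given a training sentence with a marked effect token and
tagged concept spans, each rule is the shortest undirected link path from
the effect token to the concept span's head (its rightmost token — noun
phrases are treated as head-final, expansion runs leftward). Each hop
contributes a (reduced label, direction) step; intermediate tokens
contribute their stem as a node constraint; the final step carries none and
lands on the concept placeholder (`@SUBSTANCE`, `@SYMPTOM` for
symptoms/processes, `@DISEASE`, `@BODYPART`). When several shortest paths
exist, the step sequence that is lexicographically smallest by (label,
direction, node stem) wins, making learned rulebooks deterministic. An
unreachable concept is a learning error, not a silent skip.

**Matching.** A rule is satisfied only when its whole route can be walked
from an effect token: every step follows *all* edges of its label in its
direction (set semantics — multiple simultaneous bindings are all kept),
node constraints compare stems, and terminal tokens are expanded leftward
through the entity-expansion link set to the full multi-word name. The
expansion set defaults to `{AN, A, G}` (noun-compound, adjective,
proper-name links); which links the expansion should cross is genuinely
open, so the set is configurable.

A rule may traverse tokens belonging to another tagged concept; nothing in
the matching semantics forbids it, and forbidding it would make rule
satisfaction depend on tag order.

## Entity recognition and slot repair

A semantic lexicon TSV (`term → group, semantic type`) stands in for a
full biomedical named-entity service. Lookup is surface-based (case-folded,
whitespace-normalized, *not* stemmed, to preserve names like "HCT-116"),
with a longest-known-suffix fallback for multi-word terms. After rule
extraction the recognizer:

1. drops unknown terms (the main false-positive filter);
2. moves each remaining term to the field its recognized group dictates —
   a disease bound through a symptom rule still lands in the disease field;
3. on collision (a moved term targeting a field already held by a term that
   was typed in place), keeps the in-place term and drops the mover with a
   logged warning; the same term arriving through two placeholders is a
   duplicate, not a collision;
4. fans multi-candidate slots out into one relation per substance × context
   combination, deduplicates, and rejects assemblies violating the relation
   invariants (rejections are logged, never raised).

Repair is idempotent: re-normalizing an assembled relation is a fixed point.

## Similarity measure

Four components, each mapped to a comparative value, summed to a total in
[0, 4] on a 0.5 grid:

| component | rule | default constant |
|---|---|---|
| semantic type | equal after case folding, both non-empty → 1 | — |
| structure | MCS-Tanimoto t ≥ threshold → 1; substructure → 0.5 | 0.75 |
| atomic count | Σ\|aᵢ−bᵢ\| / max(total atoms) ≤ threshold → 1 | 0.2 |
| XLogP | \|Δ\| ≤ 0.5 → 1; 0.5 < \|Δ\| < 1 → 0.5; else 0 | 0.5 / 1.0 |

Calibration notes. The atomic-count rule needs a closeness criterion; the
relative Manhattan distance with cutoff 0.2 accepts both reference pairs
(cordycepin/fludarabine at 3/32 ≈ 0.094, wogonin/fisetin formulas at
4/33 ≈ 0.121) while rejecting grossly different compositions. The
structural "similar" cutoff is set at 0.75 so that a Tanimoto of exactly
0.75 counts as similar, as the flavonoid reference pair requires. The XLogP
mid-band is interpreted as 0.5 < \|Δ\| < 1 (the half-open reading consistent
with both reference pairs); boundary values: \|Δ\| = 0.5 is similar,
\|Δ\| = 1.0 is not. All four constants live in `upkmine.config.Thresholds`
and can be overridden from a `key=value` config file.

**Structures.** SMILES strings are parsed by a subset parser (organic-subset
and bracket atoms, branches, ring closures, aromatic lowercase; bond orders,
stereo marks, charges and explicit hydrogens are accepted but not recorded)
into heavy-atom graphs. Structural similarity is the maximum common
**connected induced** subgraph under (element, aromaticity) atom
compatibility, found by McGregor-style backtracking: seeded at every
compatible atom pair, grown over the frontier with a map-or-exclude branch
per atom, with an admissible size bound for pruning. The search is exact up
to a configurable budget (40 heavy atoms by default, plus a node-expansion
cap); beyond it the result is returned as a flagged lower bound. Tests
verify the search against a brute-force oracle (exhaustive connected-subset
enumeration with `networkx` subgraph isomorphism) on all pairs of fixture
molecules ≤ 12 atoms, and the parser against RDKit atom/bond counts.

A published structural-similarity value can be fed directly into the
comparative table via `similarity_score(..., structural_t=...)`, since
printed reference values come from an external subgraph detector whose
exact variant is not recoverable. (For the wogonin/fisetin structures the
built-in search happens to reproduce the published 0.75 exactly.)

A record with a missing or unparsable attribute scores 0 on that component
with a logged warning — degraded, not fatal — so one incomplete database
entry cannot abort a corpus run.

## Hypothesis generation

Relations pair when their substances are distinct, share the effect type,
both have chemical records, and their similarity total reaches the
threshold (default 2). Each pair yields at most two candidates by
transferring the **full** (process, disease, body part) context triple — not
the body part alone — between substances: context transfer must be able to
carry a process the receiving substance was never extracted with, and
body-part-only swapping is the special case of identical processes.
Opposite-effect pairing is unsupported: no reference example licenses
transferring a context across an Increase/Reduction boundary.

Candidates equal to any extracted relation (five-field identity) are
dropped. When the same generated tuple arises from several partners, the
maximum score is kept (logged; merging rules like sum were considered and
rejected as unanchored). Ranking is descending by score with deterministic
lexicographic tie-breaks.

## Synthetic corpora

`generate_corpus(seed, n_relations, noise_rate)` emulates every external
artifact: abstracts XML (one planted sentence per abstract), parse blocks
(via the toy linker), semantic lexicon, chemical table, rulebook (learned
from eight bundled tagged training sentences) and the planted truth. Four
surface templates are used — "X *induces/reduces/increases* Y in Z",
"X *induces/…* D", "X was a potent inducer of Y", "X contributes to D" —
with vocabulary pools of invented drug-like substance names (a fraction
two-word, to exercise entity expansion) and fixed process/disease/body-part
terms. Chemical records are built pairwise: a tunable fraction of substance
pairs (default 0.6) share a chain scaffold extended by one atom, a formula
within the atomic threshold, matched semantic types and jittered XLogP —
scoring 4 by construction — while the rest draw attributes independently.
Noise adds distractor sentences with no effect word, or effect sentences
about substances absent from the lexicon, which the recognizer must reject.
Generation is deterministic per seed and byte-identical when written out.

What passing proves, and what it does not: noise-free planted corpora are
recovered with precision = recall = 1 (the learn-then-match closure of the
rule layer plus the recognizer's no-invention property), and recall never
improves as noise is added. Real abstracts are harder in ways the generator
deliberately does not model: free word order, parser failures, anaphora,
abbreviations, sense ambiguity, and lexicon gaps. The synthetic results are
self-consistency guarantees of the machinery, not performance estimates for
PubMed-scale corpora.

Problem sizes used by the default experiments: end-to-end recovery runs 50
planted relations across 5 seeds; the MCS oracle comparison covers all 45
pairs of ten fixture molecules (≤ 12 heavy atoms). Both complete in seconds.

## Known limitations

- The rulebook cannot generalize across rules (no merging, weighting or
  probabilistic matching); coverage is exactly what was tagged.
- Extraction is sentence-local; relations split across sentences by
  anaphora are invisible.
- Novelty is literal five-field inequality; paraphrased duplicates of known
  relations will surface as "novel".
- XLogP is read from the chemical table, never computed from structure.
- The MCS is atom-connectivity based; bond orders are ignored, so a single
  and a double bond between identical atom pairs are indistinguishable.
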