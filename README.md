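# upkmine

Literature-based discovery for biomedical abstracts, in the tradition of
Swanson's *Undiscovered Public Knowledge*: if one paper reports that
substance A affects process B, and another that a chemically similar
substance A′ affects B in a different setting, the two fragments together
suggest hypotheses neither paper states. `upkmine` automates that chain for
**SEPDB relations** — Substance, Effect, Process, Disease, Body part — with
the effect (Increase / Reduction) as the node connecting a substance to what
it acts on and where.

The pipeline has three stages:

1. **Extraction.** Abstracts (MEDLINE-style XML) are split into sentences;
   sentences containing an *effect word* (Porter-stem match against a small
   lexicon: induce, contribute, reduce, increase, resistant) are selected.
   Each selected sentence is viewed as a link-grammar-style graph — words as
   vertices, typed links (`S` subject, `O` object, `MV`/`J` preposition
   chains, `AN` noun compounds) as edges — and *path rules* learned from
   hand-tagged examples are traversed from the effect word to bind concept
   slots. A rule such as `induc :: S- @SUBSTANCE` reads "from the effect
   word, follow one subject link leftward; there sits the substance". A
   lexicon-based recognizer then types each bound term, drops unknown words,
   moves terms into the slot their semantic group dictates, and assembles
   SEPDB relations.
2. **Similarity.** Substance pairs are scored on four components, each
   mapped to a comparative value and summed (maximum 4):
   semantic type equality (0/1); structural similarity as the MCS-Tanimoto
   `m / (|A| + |B| − m)` over heavy-atom graphs, where `m` is the size of a
   maximum common connected subgraph (1 when t ≥ 0.75, 0.5 when one molecule
   is a substructure of the other, else 0); atomic-count closeness (1 when
   the relative Manhattan distance between element counts is ≤ 0.2); and
   XLogP closeness (1 when |Δ| ≤ 0.5, 0.5 when 0.5 < |Δ| < 1, else 0).
3. **Hypothesis generation.** For every pair of extracted relations with
   distinct substances, the same effect type, and similarity ≥ 2, two
   candidates are formed by giving each substance the *other* relation's
   (process, disease, body part) context. Candidates that restate an
   extracted relation are dropped; survivors are ranked by score.

## Worked example

The flavonoids wogonin and fisetin both increase apoptosis — one observed in
malignant T cells, the other in HCT-116 colon carcinoma cells:

```python
from upkmine import ChemicalRecord, SEPDBRelation, similarity_score
from upkmine.hypothesis import generate_hypotheses

wogonin = ChemicalRecord("Wogonin", "Organic Chemical",
                         smiles="COc1c(O)cc2oc(-c3ccccc3)cc(=O)c2c1O",
                         formula="C16H12O5", xlogp=2.74)
fisetin = ChemicalRecord("Fisetin", "Organic Chemical",
                         smiles="O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)ccc12",
                         formula="C15H10O6", xlogp=2.77)

b = similarity_score(wogonin, fisetin)
print("semtype", b.semtype_value, "| structural", b.structural_value,
      "| atomic", b.atomic_value, "| xlogp", b.xlogp_value, "| total", b.total)

extracted = [
    SEPDBRelation("Wogonin", "Increase", process="Apoptosis", body_part="Malignant T Cells"),
    SEPDBRelation("Fisetin", "Increase", process="Apoptosis", body_part="HCT-116 Cells"),
]
for h in generate_hypotheses(extracted, {"wogonin": wogonin, "fisetin": fisetin}):
    print(h.relation.to_row()[:5], "score", h.score)
```

prints

```
semtype 1.0 | structural 1.0 | atomic 1.0 | xlogp 1.0 | total 4.0
('Fisetin', 'Increase', 'Apoptosis', 'N/A', 'Malignant T Cells') score 4.0
('Wogonin', 'Increase', 'Apoptosis', 'N/A', 'HCT-116 Cells') score 4.0
```

The two molecules share an 18-atom common subgraph (MCS-Tanimoto 18/24 =
0.75), identical semantic types, near-identical composition and XLogP, so
the pair scores the maximum 4 — and the body parts are switched to produce
two novel, maximally ranked hypotheses: wogonin may increase apoptosis in
HCT-116 cells, fisetin in malignant T cells.

The same flow runs from the shell on a synthetic corpus with planted ground
truth:

```
$ upkmine simulate --seed 5 --relations 10 --noise 0.2 --out demo/data
planted 10 relations over 12 abstracts -> demo/data
$ upkmine pipeline --xml demo/data/corpus.xml --parses demo/data/parses.txt \
    --rules demo/data/rules.txt --lexicon demo/data/lexicon.tsv \
    --chem demo/data/chem.tsv --effects demo/data/effects.tsv --outdir demo/out
10 relations, 4 hypotheses -> demo/out
$ upkmine eval --extracted demo/out/relations.tsv --truth demo/data/truth.tsv
TP=10 FP=0 FN=0 precision=1.000 recall=1.000
```

`upkmine learn-rules` builds a rulebook from tagged parse blocks, and
`upkmine hypothesize` runs the discovery stage on an existing relations TSV.
See `docs/methods.md` for file formats, thresholds and design notes.

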