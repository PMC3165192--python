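"""Synthetic corpora with planted ground truth, and extraction evaluation.

Real runs of this kind of pipeline need a PubMed download, a syntactic
parser and a named-entity service. The generator here emulates all of their
artifacts — abstracts XML, parse-graph blocks, a semantic lexicon, a
chemical-record table — around a list of *planted* SEPDB relations whose
recovery can be checked exactly. Sentences follow a small set of surface
templates observed in real abstracts ("X induces Y in Z", "X was a potent
inducer of Y", ...), each with a fixed linkage, so the rulebook learned from
the bundled training sentences is small and interpretable.

Evaluation is standard set-based precision/recall over five-field relation
identity: true positives are planted relations recovered verbatim, false
positives are extracted relations not planted, false negatives are planted
relations missed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chemsim import ChemicalRecord, write_chem_table
from .corpus import AbstractRecord, EffectLexicon, write_medline_xml
from .parsegraph import (
    LinkageTemplate,
    ParseGraph,
    TaggedSentence,
    tag_with_template,
    toy_linker,
    write_parse_file,
)
from .recognizer import SemanticLexicon, SEPDBRelation, write_relations
from .rules import ExtractionRule, learn_rules, write_rulebook

__all__ = [
    "TEMPLATES",
    "TRAINING_SENTENCES",
    "EvalResult",
    "PlantedCorpus",
    "default_rulebook",
    "training_tagged_sentences",
    "generate_corpus",
    "evaluate",
]

_SVO_VERBS = "induces|reduces|increases"

#: Fixture linkage templates. Labels follow link-grammar conventions:
#: S subject, O object, MV verb modifier, J preposition object, D determiner,
#: A adjective, AN noun compound.
TEMPLATES: tuple[LinkageTemplate, ...] = (
    LinkageTemplate(
        name="svo_in",
        skeleton=("{SUBSTANCE}", _SVO_VERBS, "{OBJECT}", "in", "{BODYPART}"),
        links=((0, 1, "Ss"), (1, 2, "Os"), (1, 3, "MVp"), (3, 4, "Js")),
        effect_item=1,
        placeholders={
            "SUBSTANCE": "@SUBSTANCE",
            "OBJECT": "@SYMPTOM",
            "BODYPART": "@BODYPART",
        },
    ),
    LinkageTemplate(
        name="inducer_of",
        skeleton=("{SUBSTANCE}", "was", "a", "potent", "inducer", "of", "{OBJECT}"),
        links=(
            (0, 1, "Ss"),
            (1, 4, "Ost"),
            (2, 4, "Ds"),
            (3, 4, "A"),
            (4, 5, "Mp"),
            (5, 6, "Js"),
        ),
        effect_item=4,
        placeholders={"SUBSTANCE": "@SUBSTANCE", "OBJECT": "@SYMPTOM"},
    ),
    LinkageTemplate(
        name="contributes_to",
        skeleton=("{SUBSTANCE}", "contributes", "to", "{DISEASE}"),
        links=((0, 1, "Ss"), (1, 2, "MVp"), (2, 3, "Js")),
        effect_item=1,
        placeholders={"SUBSTANCE": "@SUBSTANCE", "DISEASE": "@DISEASE"},
    ),
    LinkageTemplate(
        name="svo_disease",
        skeleton=("{SUBSTANCE}", _SVO_VERBS, "{DISEASE}"),
        links=((0, 1, "Ss"), (1, 2, "Os")),
        effect_item=1,
        placeholders={"SUBSTANCE": "@SUBSTANCE", "DISEASE": "@DISEASE"},
    ),
)

#: Hand-tagged training sentences the default rulebook is learned from.
TRAINING_SENTENCES: tuple[str, ...] = (
    "tolfenamic acid induces Sp protein degradation in cancer cell lines.",
    "tolfenamic acid reduces Sp protein degradation in cancer cell lines.",
    "tolfenamic acid increases Sp protein degradation in cancer cell lines.",
    "docetaxel was a potent inducer of apoptosis.",
    "tolfenamic acid contributes to leukemia.",
    "tolfenamic acid induces leukemia.",
    "tolfenamic acid reduces leukemia.",
    "tolfenamic acid increases leukemia.",
)


def training_tagged_sentences() -> list[TaggedSentence]:
    return [
        tag_with_template(sentence, TEMPLATES, sentence_id=f"train:{i}")
        for i, sentence in enumerate(TRAINING_SENTENCES)
    ]


def default_rulebook() -> set[ExtractionRule]:
    """Rules learned from the bundled training sentences (deterministic)."""
    rules: set[ExtractionRule] = set()
    for tagged in training_tagged_sentences():
        rules |= learn_rules(tagged)
    return rules


# ---------------------------------------------------------------------------
# Vocabulary pools
# ---------------------------------------------------------------------------

_NAME_PREFIXES = (
    "Alvo", "Beri", "Cato", "Dexi", "Eflo", "Gani", "Helo", "Irba", "Julo",
    "Kema", "Lora", "Mipo", "Nevo", "Oxa", "Pera", "Quina", "Rilo", "Sulfa",
    "Tebo", "Uvi", "Velo", "Xan", "Zeta",
)
_NAME_SUFFIXES = (
    "cillin", "statin", "fenac", "profen", "mycin", "taxel", "tinib",
    "parin", "navir", "zomib",
)

_PROCESSES = (
    "apoptosis", "autophagy", "angiogenesis", "cell proliferation",
    "DNA fragmentation", "caspase activation", "oxidative stress",
    "cytokine release", "histone acetylation", "tumor invasion",
)
_DISEASES = (
    "leukemia", "melanoma", "glioma", "lymphoma", "carcinoma",
    "neuropathy", "fibrosis", "osteosarcoma",
)
_BODY_PARTS = (
    "HCT-116 cells", "tumor cells", "malignant T cells", "liver tissue",
    "bone marrow", "colon epithelium", "lung fibroblasts", "breast carcinoma cells",
)
_SEMANTIC_TYPES = (
    "Organic Chemical", "Pharmacologic Substance",
    "Amino Acid, Peptide, or Protein",
)
_DISTRACTORS = (
    "The study enrolled twelve patients over two years.",
    "Samples were analyzed by liquid chromatography.",
    "The trial design followed standard ethical guidelines.",
    "Cell cultures were maintained at thirty-seven degrees.",
    "The cohort was followed for eighteen months.",
)


@dataclass(frozen=True)
class EvalResult:
    """Set-based extraction scores over five-field relation identity."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    #: True when a denominator was zero and the proportion was reported as 0.
    precision_undefined: bool = False
    recall_undefined: bool = False


def evaluate(
    extracted: Iterable[SEPDBRelation], truth: Iterable[SEPDBRelation]
) -> EvalResult:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN); undefined ratios report 0
    with a flag."""
    extracted_keys = {rel.key() for rel in extracted}
    truth_keys = {rel.key() for rel in truth}
    tp = len(extracted_keys & truth_keys)
    fp = len(extracted_keys - truth_keys)
    fn = len(truth_keys - extracted_keys)
    precision_undefined = tp + fp == 0
    recall_undefined = tp + fn == 0
    return EvalResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=0.0 if precision_undefined else tp / (tp + fp),
        recall=0.0 if recall_undefined else tp / (tp + fn),
        precision_undefined=precision_undefined,
        recall_undefined=recall_undefined,
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


@dataclass
class PlantedCorpus:
    """All pipeline inputs for one synthetic run, plus the planted truth."""

    seed: int
    records: list[AbstractRecord]
    graphs: dict[str, ParseGraph]
    lexicon: SemanticLexicon
    effect_lexicon: EffectLexicon
    chem_table: dict[str, ChemicalRecord]
    rulebook: set[ExtractionRule]
    truth: list[SEPDBRelation]
    templates: tuple[LinkageTemplate, ...] = TEMPLATES

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize every input as a file; byte-identical per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": outdir / "corpus.xml",
            "parses": outdir / "parses.txt",
            "lexicon": outdir / "lexicon.tsv",
            "effects": outdir / "effects.tsv",
            "chem": outdir / "chem.tsv",
            "rules": outdir / "rules.txt",
            "truth": outdir / "truth.tsv",
        }
        write_medline_xml(self.records, paths["corpus"])
        blocks = [self.graphs[k] for k in sorted(self.graphs)]
        write_parse_file(blocks, paths["parses"])
        self.lexicon.save(paths["lexicon"])
        self.effect_lexicon.save(paths["effects"])
        write_chem_table(self.chem_table.values(), paths["chem"])
        write_rulebook(self.rulebook, paths["rules"])
        write_relations(self.truth, paths["truth"])
        return paths


def _make_substances(rng: random.Random, count: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < count:
        name = rng.choice(_NAME_PREFIXES) + rng.choice(_NAME_SUFFIXES)
        if rng.random() < 0.3:
            name += " acid"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _make_chem_records(
    rng: random.Random, substances: Sequence[str], similar_fraction: float
) -> dict[str, ChemicalRecord]:
    """Chemical records with a controlled fraction of similar pairs.

    Consecutive substances are considered in pairs; a similar pair shares a
    chain scaffold extended by one atom (substructure, MCS-Tanimoto >= 0.83),
    a formula perturbed within the atomic-count threshold, matched semantic
    types, and an XLogP jitter inside the Similar band — scoring 4 by
    construction. The rest draw every attribute independently.
    """
    records: dict[str, ChemicalRecord] = {}

    def solo(name: str) -> ChemicalRecord:
        length = rng.randint(3, 10)
        hetero = rng.choice(["N", "O", "S"])
        smiles = "C" * length + hetero
        formula = f"C{length}H{2 * length + 1}{hetero}"
        return ChemicalRecord(
            name=name,
            semantic_type=rng.choice(_SEMANTIC_TYPES),
            smiles=smiles,
            formula=formula,
            xlogp=round(rng.uniform(-3.0, 5.0), 2),
        )

    index = 0
    while index < len(substances):
        if index + 1 < len(substances) and rng.random() < similar_fraction:
            first, second = substances[index], substances[index + 1]
            length = rng.randint(5, 9)
            base_x = round(rng.uniform(-2.0, 4.0), 2)
            semtype = rng.choice(_SEMANTIC_TYPES)
            records[first] = ChemicalRecord(
                name=first,
                semantic_type=semtype,
                smiles="C" * (length - 1) + "O",
                formula=f"C{length - 1}H{2 * (length - 1)}O",
                xlogp=base_x,
            )
            records[second] = ChemicalRecord(
                name=second,
                semantic_type=semtype,
                smiles="C" * length + "O",
                formula=f"C{length}H{2 * length}O",
                xlogp=round(base_x + rng.uniform(-0.4, 0.4), 2),
            )
            index += 2
        else:
            records[substances[index]] = solo(substances[index])
            index += 1
    return records


def _plant_one(
    rng: random.Random,
    substances: Sequence[str],
) -> tuple[str, SEPDBRelation]:
    """One template sentence and the relation it realizes."""
    kind = rng.choice(("svo_in", "svo_disease", "inducer_of", "contributes_to"))
    substance = rng.choice(substances)
    if kind == "svo_in":
        verb = rng.choice(("induces", "reduces", "increases"))
        process = rng.choice(_PROCESSES)
        body = rng.choice(_BODY_PARTS)
        sentence = f"{substance} {verb} {process} in {body}."
        etype = "Reduction" if verb == "reduces" else "Increase"
        relation = SEPDBRelation(substance, etype, process=process, body_part=body)
    elif kind == "svo_disease":
        verb = rng.choice(("induces", "reduces", "increases"))
        disease = rng.choice(_DISEASES)
        sentence = f"{substance} {verb} {disease}."
        etype = "Reduction" if verb == "reduces" else "Increase"
        relation = SEPDBRelation(substance, etype, disease=disease)
    elif kind == "inducer_of":
        process = rng.choice(_PROCESSES)
        sentence = f"{substance} was a potent inducer of {process}."
        relation = SEPDBRelation(substance, "Increase", process=process)
    else:
        disease = rng.choice(_DISEASES)
        sentence = f"{substance} contributes to {disease}."
        relation = SEPDBRelation(substance, "Increase", disease=disease)
    return sentence, relation


def generate_corpus(
    seed: int,
    n_relations: int,
    noise_rate: float = 0.0,
    similar_fraction: float = 0.6,
    n_substances: int | None = None,
) -> PlantedCorpus:
    """A complete synthetic pipeline input with ``n_relations`` planted truths.

    ``noise_rate`` adds that fraction of extra distractor sentences — either
    with no effect word at all or mentioning a substance absent from the
    lexicon (which the recognizer must reject). ``similar_fraction`` controls
    how many substance pairs are chemically similar and can seed hypotheses.
    Deterministic per seed, byte-identical when written out.
    """
    if n_relations < 0:
        raise ValueError("n_relations must be >= 0")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    rng = random.Random(seed)
    if n_substances is None:
        n_substances = max(4, n_relations // 3 + 2)
    substances = _make_substances(rng, n_substances)
    chem_table_by_name = _make_chem_records(rng, substances, similar_fraction)

    lexicon_entries: dict[str, tuple[str, str]] = {}
    for name in substances:
        lexicon_entries[name] = ("SUBSTANCE", chem_table_by_name[name].semantic_type)
    for process in _PROCESSES:
        lexicon_entries[process] = ("PROCESS", "Cell Function")
    for disease in _DISEASES:
        lexicon_entries[disease] = ("DISEASE", "Neoplastic Process")
    for body in _BODY_PARTS:
        lexicon_entries[body] = ("BODYPART", "Cell")
    lexicon = SemanticLexicon(lexicon_entries)

    truth: list[SEPDBRelation] = []
    seen_keys: set[tuple[str, ...]] = set()
    sentences: list[tuple[str, bool]] = []  # (sentence, needs parse block)
    attempts = 0
    while len(truth) < n_relations:
        attempts += 1
        if attempts > 200 * max(1, n_relations):
            raise ValueError(
                "cannot plant that many distinct relations with this vocabulary"
            )
        sentence, relation = _plant_one(rng, substances)
        if relation.key() in seen_keys:
            continue
        seen_keys.add(relation.key())
        truth.append(relation)
        sentences.append((sentence, True))

    n_noise = round(noise_rate * n_relations)
    for i in range(n_noise):
        if rng.random() < 0.5:
            sentences.append((rng.choice(_DISTRACTORS), False))
        else:
            # effect sentence about an unknown substance: extracted by rules,
            # then rejected by the recognizer
            process = rng.choice(_PROCESSES)
            sentences.append(
                (f"Zetrixol{i} induces {process} in unknown specimens.", True)
            )
    rng.shuffle(sentences)

    records: list[AbstractRecord] = []
    graphs: dict[str, ParseGraph] = {}
    for i, (sentence, needs_parse) in enumerate(sentences):
        pmid = str(90000000 + i)
        records.append(
            AbstractRecord(pmid=pmid, title=f"Synthetic abstract {i}", abstract=sentence)
        )
        if needs_parse:
            sentence_id = f"{pmid}:0"
            graphs[sentence_id] = toy_linker(sentence, TEMPLATES, sentence_id)

    return PlantedCorpus(
        seed=seed,
        records=records,
        graphs=graphs,
        lexicon=lexicon,
        effect_lexicon=EffectLexicon.default(),
        chem_table={
            key: rec
            for key, rec in (
                (name.casefold(), chem_table_by_name[name]) for name in substances
            )
        },
        rulebook=default_rulebook(),
        truth=truth,
    )
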