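"""End-to-end orchestration: abstracts -> relations -> hypotheses."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chemsim import ChemicalRecord, read_chem_table
from .config import DEFAULT_THRESHOLDS, Thresholds
from .corpus import AbstractRecord, EffectLexicon, read_medline_xml, select_sentences
from .fixtures import PlantedCorpus
from .hypothesis import Hypothesis, generate_hypotheses
from .parsegraph import ParseGraph, TaggedSentence, read_parse_file
from .recognizer import SemanticLexicon, SEPDBRelation, normalize
from .rules import ExtractionRule, apply_rulebook, parse_rulebook

__all__ = ["extract_relations", "extract_from_files", "run_corpus", "hypothesize"]

logger = logging.getLogger(__name__)


def extract_relations(
    records: Sequence[AbstractRecord],
    graphs: Mapping[str, ParseGraph],
    rulebook: Iterable[ExtractionRule],
    lexicon: SemanticLexicon,
    effect_lexicon: EffectLexicon | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[SEPDBRelation]:
    """Select effect sentences, apply rules, recognize entities, assemble.

    ``graphs`` maps sentence ids (``pmid:index``) to parse graphs; effect
    sentences without a graph are skipped with a warning (the adapter's
    parser failed them). Output is deduplicated on five-field identity,
    first provenance kept.
    """
    effect_lexicon = effect_lexicon or EffectLexicon.default()
    rulebook = list(rulebook)
    relations: list[SEPDBRelation] = []
    seen: set[tuple[str, ...]] = set()
    for match in select_sentences(records, effect_lexicon):
        graph = graphs.get(match.sentence_id)
        if graph is None:
            logger.warning("no parse graph for sentence %s; skipped", match.sentence_id)
            continue
        raw = apply_rulebook(
            graph, match, rulebook, expansion_labels=thresholds.expansion_links
        )
        if raw is None:
            continue
        for relation in normalize(raw, lexicon, effect_lexicon):
            if relation.key() not in seen:
                seen.add(relation.key())
                relations.append(relation)
    return relations


def _graphs_from_file(path: str | Path) -> dict[str, ParseGraph]:
    graphs: dict[str, ParseGraph] = {}
    for block in read_parse_file(path):
        graph = block.graph if isinstance(block, TaggedSentence) else block
        graphs[graph.sentence_id] = graph
    return graphs


def extract_from_files(
    xml_path: str | Path,
    parse_path: str | Path,
    rules_path: str | Path,
    lexicon_path: str | Path,
    effects_path: str | Path | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[SEPDBRelation]:
    """File-based variant of :func:`extract_relations` (the CLI's backend)."""
    return extract_relations(
        records=read_medline_xml(xml_path),
        graphs=_graphs_from_file(parse_path),
        rulebook=parse_rulebook(rules_path),
        lexicon=SemanticLexicon.load(lexicon_path),
        effect_lexicon=(
            EffectLexicon.load(effects_path) if effects_path else None
        ),
        thresholds=thresholds,
    )


def run_corpus(
    corpus: PlantedCorpus, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[SEPDBRelation]:
    """Extraction over an in-memory synthetic corpus."""
    return extract_relations(
        records=corpus.records,
        graphs=corpus.graphs,
        rulebook=corpus.rulebook,
        lexicon=corpus.lexicon,
        effect_lexicon=corpus.effect_lexicon,
        thresholds=thresholds,
    )


def hypothesize(
    relations: Sequence[SEPDBRelation],
    chem_table: Mapping[str, ChemicalRecord] | str | Path,
    threshold: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[Hypothesis]:
    """Ranked novel hypotheses from extracted relations and a chemical table."""
    if not isinstance(chem_table, Mapping):
        chem_table = read_chem_table(chem_table)
    return generate_hypotheses(relations, chem_table, threshold, thresholds)
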