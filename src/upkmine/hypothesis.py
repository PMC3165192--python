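"""Hypothesis generation by relation recombination.

The discovery step follows the ABC pattern of literature-based discovery:
when two extracted relations involve distinct but chemically similar
substances acting in the same direction, each substance plausibly operates
in the other's context. A candidate hypothesis takes (substance, effect
type) from one relation and the full (process, disease, body part) context
from the other; its score is the pair's similarity total, used both for the
survival threshold (default 2 of a maximum 4) and for ranking. Candidates
that merely restate an already-extracted relation are dropped (the novelty
contract).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chemsim import ChemicalRecord, SimilarityBreakdown, _norm_name, similarity_score
from .config import DEFAULT_THRESHOLDS, Thresholds
from .recognizer import SEPDBRelation

__all__ = [
    "Hypothesis",
    "candidate_pairs",
    "recombine",
    "rank",
    "generate_hypotheses",
    "write_hypotheses",
]

logger = logging.getLogger(__name__)

HYPOTHESIS_COLUMNS = (
    "substance",
    "effect_type",
    "process",
    "disease",
    "body_part",
    "score",
    "sources",
)


@dataclass(frozen=True)
class Hypothesis:
    """A recombined relation, its pair-similarity score and its parents."""

    relation: SEPDBRelation
    score: float
    sources: tuple[str, str]
    partner_substance: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 4.0:
            raise ValueError(f"score {self.score} outside [0, 4]")


def candidate_pairs(
    relations: Sequence[SEPDBRelation],
    chem_table: Mapping[str, ChemicalRecord],
    threshold: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[tuple[SEPDBRelation, SEPDBRelation, SimilarityBreakdown]]:
    """Unordered relation pairs whose substances are similar enough to swap.

    A pair qualifies when the substances are distinct, share the effect type,
    both have chemical records, and their similarity total reaches the
    threshold (default 2). Substances missing from the table are skipped with
    a warning. Pair similarity is cached per substance pair.
    """
    if threshold is None:
        threshold = thresholds.score_threshold
    if not 0.0 <= threshold <= 4.0:
        raise ValueError(f"threshold {threshold} outside [0, 4]")
    cache: dict[frozenset[str], SimilarityBreakdown] = {}
    missing: set[str] = set()
    pairs: list[tuple[SEPDBRelation, SEPDBRelation, SimilarityBreakdown]] = []
    for r1, r2 in combinations(relations, 2):
        n1, n2 = _norm_name(r1.substance), _norm_name(r2.substance)
        if n1 == n2 or r1.effect_type != r2.effect_type:
            continue
        skip = False
        for name in (n1, n2):
            if name not in chem_table:
                if name not in missing:
                    missing.add(name)
                    logger.warning("substance %r has no chemical record; skipped", name)
                skip = True
        if skip:
            continue
        pair_key = frozenset((n1, n2))
        if pair_key not in cache:
            cache[pair_key] = similarity_score(
                chem_table[n1], chem_table[n2], thresholds
            )
        if cache[pair_key].total >= threshold:
            pairs.append((r1, r2, cache[pair_key]))
    return pairs


def _swap(
    source: SEPDBRelation, context: SEPDBRelation
) -> SEPDBRelation:
    return SEPDBRelation(
        substance=source.substance,
        effect_type=source.effect_type,
        process=context.process,
        disease=context.disease,
        body_part=context.body_part,
        pmid="",
        sentence="",
    )


def recombine(
    pair: tuple[SEPDBRelation, SEPDBRelation, SimilarityBreakdown],
    extracted: Iterable[SEPDBRelation] = (),
) -> set[Hypothesis]:
    """Up to two hypotheses from one qualifying pair.

    Each parent's substance and effect type are attached to the *other*
    parent's full (process, disease, body part) context. Candidates whose
    five-field tuple already appears among the extracted relations — which
    always includes both parents — are dropped.
    """
    r1, r2, breakdown = pair
    known = {rel.key() for rel in extracted}
    known.add(r1.key())
    known.add(r2.key())
    out: set[Hypothesis] = set()
    for source, context in ((r1, r2), (r2, r1)):
        candidate = _swap(source, context)
        if candidate.key() in known:
            continue
        out.add(
            Hypothesis(
                relation=candidate,
                score=breakdown.total,
                sources=(source.rel_id(), context.rel_id()),
                partner_substance=context.substance,
            )
        )
    return out


def _tie_key(h: Hypothesis) -> tuple[str, str, str, str]:
    k = h.relation.key()
    return (k[0], k[2], k[3], k[4])


def rank(hypotheses: Iterable[Hypothesis]) -> list[Hypothesis]:
    """Descending by score; ties broken lexicographically by the relation
    fields (substance, process, disease, body part). Deterministic."""
    return sorted(hypotheses, key=lambda h: (-h.score, _tie_key(h)))


def generate_hypotheses(
    relations: Sequence[SEPDBRelation],
    chem_table: Mapping[str, ChemicalRecord],
    threshold: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[Hypothesis]:
    """End-to-end: pair, recombine, deduplicate, rank.

    When the same generated five-field tuple arises from several partners,
    the highest-scoring instance is kept (logged, since the choice of merge
    rule is a judgement call).
    """
    by_tuple: dict[tuple[str, ...], Hypothesis] = {}
    for pair in candidate_pairs(relations, chem_table, threshold, thresholds):
        for hyp in recombine(pair, relations):
            key = hyp.relation.key()
            if key in by_tuple:
                logger.info(
                    "duplicate hypothesis %s from multiple partners; keeping max score",
                    key,
                )
                if hyp.score <= by_tuple[key].score:
                    continue
            by_tuple[key] = hyp
    return rank(by_tuple.values())


def write_hypotheses(hypotheses: Iterable[Hypothesis], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HYPOTHESIS_COLUMNS)
        for hyp in hypotheses:
            rel = hyp.relation
            writer.writerow(
                (
                    rel.substance,
                    rel.effect_type,
                    rel.process or "N/A",
                    rel.disease or "N/A",
                    rel.body_part or "N/A",
                    f"{hyp.score:g}",
                    ";".join(hyp.sources),
                )
            )
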