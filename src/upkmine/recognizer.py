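"""Entity typing and SEPDB relation assembly.

A semantic lexicon file (term -> concept group + UMLS-style semantic type)
stands in for a full named-entity recognizer. It serves two purposes after
rule-based extraction: unknown words are dropped (cutting false positives),
and a term whose recognized group disagrees with the slot a rule bound it to
is shifted into the correct slot — a disease extracted through a symptom rule
still ends up in the disease field.

The assembled record is an SEPDB relation: Substance, Effect type, Process,
Disease, Body part, with the effect as the connector. A relation must name a
substance and at least one of process/disease; absent fields render as N/A.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import EFFECT_TYPES, EffectLexicon
from .rules import RawExtraction

__all__ = [
    "GROUPS",
    "SemanticLexicon",
    "SEPDBRelation",
    "LexiconFormatError",
    "recognize",
    "effect_type",
    "normalize",
    "write_relations",
    "read_relations",
]

logger = logging.getLogger(__name__)

GROUPS = ("SUBSTANCE", "PROCESS", "DISEASE", "BODYPART")

#: placeholder -> relation field; @SYMPTOM covers symptoms and processes.
PLACEHOLDER_FIELD = {
    "@SUBSTANCE": "substance",
    "@SYMPTOM": "process",
    "@DISEASE": "disease",
    "@BODYPART": "body_part",
}

GROUP_FIELD = {
    "SUBSTANCE": "substance",
    "PROCESS": "process",
    "DISEASE": "disease",
    "BODYPART": "body_part",
}

RELATION_COLUMNS = (
    "substance",
    "effect_type",
    "process",
    "disease",
    "body_part",
    "pmid",
    "sentence",
)


class LexiconFormatError(ValueError):
    """Malformed semantic lexicon file."""


def _norm_term(term: str) -> str:
    return re.sub(r"\s+", " ", term).strip().casefold()


@dataclass
class SemanticLexicon:
    """Case-folded term -> (concept group, semantic type string)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, tuple[str, str]] = {}
        for term, (group, semtype) in self.entries.items():
            if group not in GROUPS:
                raise LexiconFormatError(f"unknown group {group!r} for {term!r}")
            key = _norm_term(term)
            if key in normalized and normalized[key] != (group, semtype):
                raise LexiconFormatError(f"conflicting entries for {key!r}")
            normalized[key] = (group, semtype)
        self.entries = normalized

    @classmethod
    def load(cls, path: str | Path) -> "SemanticLexicon":
        """TSV ``term<TAB>group<TAB>semantic_type``; ``#`` comments allowed."""
        entries: dict[str, tuple[str, str]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].rstrip()
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected 'term<TAB>group<TAB>semantic_type'"
                )
            entries[parts[0]] = (parts[1].strip(), parts[2].strip())
        return cls(entries)

    def save(self, path: str | Path) -> None:
        lines = [
            f"{term}\t{group}\t{semtype}"
            for term, (group, semtype) in sorted(self.entries.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def __len__(self) -> int:
        return len(self.entries)


def recognize(
    term: str, lexicon: SemanticLexicon
) -> tuple[str, str] | None:
    """(group, semantic type) for a term, or ``None`` when unknown.

    Lookup is exact on the case-folded, whitespace-normalized surface (no
    stemming, preserving names like "HCT-116"). Multi-word terms fall back to
    their longest known suffix, so "tolfenamic acid" resolves through an
    entry for either the full name or the head word "acid".
    """
    key = _norm_term(term)
    if key in lexicon.entries:
        return lexicon.entries[key]
    words = key.split(" ")
    for start in range(1, len(words)):
        suffix = " ".join(words[start:])
        if suffix in lexicon.entries:
            return lexicon.entries[suffix]
    return None


def effect_type(effect_stem: str, lexicon: EffectLexicon) -> str:
    """Increase/Reduction label for an effect-word stem; unknown stems raise."""
    if effect_stem not in lexicon:
        raise LookupError(f"effect stem {effect_stem!r} not in effect lexicon")
    return lexicon[effect_stem]


@dataclass(frozen=True)
class SEPDBRelation:
    """One Substance–Effect–Process–Disease–BodyPart record with provenance."""

    substance: str
    effect_type: str
    process: str | None = None
    disease: str | None = None
    body_part: str | None = None
    pmid: str = ""
    sentence: str = ""

    def __post_init__(self) -> None:
        if not self.substance:
            raise ValueError("relation requires a substance")
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect type {self.effect_type!r}")
        if self.process is None and self.disease is None:
            raise ValueError("relation requires a process or a disease")

    def key(self) -> tuple[str, str, str, str, str]:
        """Normalized five-field identity used for novelty and evaluation."""
        return (
            _norm_term(self.substance),
            self.effect_type.casefold(),
            _norm_term(self.process or "N/A"),
            _norm_term(self.disease or "N/A"),
            _norm_term(self.body_part or "N/A"),
        )

    def rel_id(self) -> str:
        return "|".join(self.key()) + (f"|{self.pmid}" if self.pmid else "")

    def to_row(self) -> tuple[str, ...]:
        return (
            self.substance,
            self.effect_type,
            self.process or "N/A",
            self.disease or "N/A",
            self.body_part or "N/A",
            self.pmid or "N/A",
            self.sentence,
        )


def normalize(
    raw: RawExtraction,
    lexicon: SemanticLexicon,
    effect_lexicon: EffectLexicon | None = None,
) -> list[SEPDBRelation]:
    """Type, repair and assemble raw slot bindings into SEPDB relations.

    Unknown terms are dropped. A term recognized as a different group than
    its slot moves to that group's field; when the move lands in a field
    already held by a term that was typed in place, the in-place term wins
    and the mover is dropped with a warning. Multi-candidate slots fan out
    into one relation per substance x context combination, deduplicated.
    Returns ``[]`` (a rejection, with the reason logged) when no valid
    relation can be assembled.
    """
    effect_lexicon = effect_lexicon or EffectLexicon.default()
    try:
        etype = effect_type(raw.effect_stem, effect_lexicon)
    except LookupError as exc:
        logger.warning("rejected %s: %s", raw.pmid, exc)
        return []

    # (term, original field, recognized field) for each known slot term
    typed: list[tuple[str, str, str]] = []
    for placeholder, terms in raw.slots.items():
        origin = PLACEHOLDER_FIELD[placeholder]
        for term in terms:
            hit = recognize(term, lexicon)
            if hit is None:
                logger.info("dropping unknown term %r (pmid %s)", term, raw.pmid)
                continue
            typed.append((term, origin, GROUP_FIELD[hit[0]]))

    fields: dict[str, list[str]] = {f: [] for f in GROUP_FIELD.values()}
    native_terms: dict[str, set[str]] = {}
    for term, origin, target in typed:
        if origin == target:
            native_terms.setdefault(target, set()).add(_norm_term(term))
    for term, origin, target in typed:
        if origin != target and target in native_terms:
            # a different term already holds the slot it was typed in: drop;
            # the same term arriving through another placeholder is a dup
            if _norm_term(term) not in native_terms[target]:
                logger.warning(
                    "dropping %r: repaired into occupied %s slot (pmid %s)",
                    term, target, raw.pmid,
                )
            continue
        if term not in fields[target]:
            fields[target].append(term)

    if not fields["substance"]:
        logger.info("rejected %s: no recognized substance", raw.pmid)
        return []
    relations: list[SEPDBRelation] = []
    seen: set[tuple[str, ...]] = set()
    for substance, process, disease, body_part in product(
        fields["substance"],
        fields["process"] or [None],
        fields["disease"] or [None],
        fields["body_part"] or [None],
    ):
        if process is None and disease is None:
            continue
        rel = SEPDBRelation(
            substance=substance,
            effect_type=etype,
            process=process,
            disease=disease,
            body_part=body_part,
            pmid=raw.pmid,
            sentence=raw.sentence,
        )
        if rel.key() not in seen:
            seen.add(rel.key())
            relations.append(rel)
    if not relations:
        logger.info("rejected %s: no process or disease survived", raw.pmid)
    return relations


def write_relations(
    relations: Iterable[SEPDBRelation], path: str | Path
) -> None:
    """TSV with header; absent fields rendered N/A."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RELATION_COLUMNS)
        for rel in relations:
            writer.writerow(rel.to_row())


def _denull(value: str) -> str | None:
    return None if value in ("", "N/A") else value


def read_relations(path: str | Path) -> list[SEPDBRelation]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != RELATION_COLUMNS:
            raise ValueError(f"{path}: expected header {' '.join(RELATION_COLUMNS)}")
        out: list[SEPDBRelation] = []
        for row in reader:
            if not row:
                continue
            sub, etype, proc, dis, body, pmid, sentence = row
            out.append(
                SEPDBRelation(
                    substance=sub,
                    effect_type=etype,
                    process=_denull(proc),
                    disease=_denull(dis),
                    body_part=_denull(body),
                    pmid="" if pmid == "N/A" else pmid,
                    sentence=sentence,
                )
            )
    return out
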