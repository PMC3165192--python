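"""Abstract ingestion and effect-sentence selection.

Reads MEDLINE-style XML (a minimal ``PubmedArticleSet`` dialect: ``PMID``,
``ArticleTitle`` and ``AbstractText`` elements; everything else is ignored),
splits abstracts into sentences, and keeps the sentences that contain an
*effect word* — a verb such as "induce" or "reduce" that connects a substance
to the process or disease it acts on. Matching is stem-based and
case-insensitive, so "induces", "inducer" and "Induced" all hit the lexicon
entry for "induce".
"""

from __future__ import annotations

import re
import string
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .stemming import stem

__all__ = [
    "AbstractRecord",
    "EffectLexicon",
    "SentenceMatch",
    "CorpusFormatError",
    "read_medline_xml",
    "write_medline_xml",
    "split_sentences",
    "tokenize",
    "select_sentences",
]

#: Effect words and the direction of action they encode. The five entries are
#: the core connector vocabulary of the SEPDB model (Increase vs Reduction).
DEFAULT_EFFECT_WORDS: tuple[tuple[str, str], ...] = (
    ("induce", "Increase"),
    ("contribute", "Increase"),
    ("reduce", "Reduction"),
    ("increase", "Increase"),
    ("resistant", "Reduction"),
)

EFFECT_TYPES = frozenset({"Increase", "Reduction"})


class CorpusFormatError(ValueError):
    """Raised for structurally invalid corpus or lexicon files."""


@dataclass(frozen=True)
class AbstractRecord:
    """One article: PubMed identifier, title, abstract text."""

    pmid: str
    title: str = ""
    abstract: str = ""


@dataclass(frozen=True)
class SentenceMatch:
    """A sentence selected because one of its tokens stems to an effect word."""

    pmid: str
    sentence: str
    effect_surface: str
    effect_stem: str
    effect_type: str
    sent_index: int = 0

    @property
    def sentence_id(self) -> str:
        """Identifier joining the sentence to its parse-graph block."""
        return f"{self.pmid}:{self.sent_index}"


@dataclass
class EffectLexicon:
    """Mapping from effect-word stem to effect type (Increase / Reduction).

    ``sources`` keeps the surface word each stem came from, so saving a
    lexicon writes words (which restem identically on reload), not stems.
    """

    entries: dict[str, str] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if value not in EFFECT_TYPES:
                raise CorpusFormatError(f"unknown effect type {value!r} for {key!r}")
            if key != key.casefold():
                raise CorpusFormatError(f"effect stem {key!r} is not case-folded")
        for key in self.entries:
            self.sources.setdefault(key, key)

    @classmethod
    def from_words(cls, pairs: Iterable[tuple[str, str]]) -> "EffectLexicon":
        """Build from (surface word, type) pairs; words are stemmed at load."""
        entries: dict[str, str] = {}
        sources: dict[str, str] = {}
        for word, etype in pairs:
            key = stem(word)
            entries[key] = etype
            sources[key] = word.casefold()
        return cls(entries, sources)

    @classmethod
    def default(cls) -> "EffectLexicon":
        return cls.from_words(DEFAULT_EFFECT_WORDS)

    @classmethod
    def load(cls, path: str | Path) -> "EffectLexicon":
        """Read a two-column TSV ``word<TAB>type``; ``#`` starts a comment."""
        pairs: list[tuple[str, str]] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 'word<TAB>type'")
            pairs.append((parts[0].strip(), parts[1].strip()))
        return cls.from_words(pairs)

    def save(self, path: str | Path) -> None:
        lines = [
            f"{self.sources[k]}\t{v}" for k, v in sorted(self.entries.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def __contains__(self, stem_: str) -> bool:
        return stem_ in self.entries

    def __getitem__(self, stem_: str) -> str:
        return self.entries[stem_]

    def __len__(self) -> int:
        return len(self.entries)


def _element_text(elem: ET.Element | None) -> str:
    if elem is None:
        return ""
    return re.sub(r"\s+", " ", "".join(elem.itertext())).strip()


def read_medline_xml(path: str | Path) -> list[AbstractRecord]:
    """Parse a PubmedArticleSet file into abstract records, in document order.

    Raises :class:`xml.etree.ElementTree.ParseError` (with line information)
    on malformed XML and :class:`CorpusFormatError` when an article lacks a
    PMID or a PMID repeats.
    """
    tree = ET.parse(str(path))
    root = tree.getroot()
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    for index, article in enumerate(root.iter("PubmedArticle")):
        pmid = _element_text(article.find(".//PMID"))
        if not pmid:
            raise CorpusFormatError(f"{path}: article #{index} has no PMID element")
        if pmid in seen:
            raise CorpusFormatError(f"{path}: duplicate PMID {pmid}")
        seen.add(pmid)
        title = _element_text(article.find(".//ArticleTitle"))
        abstract = " ".join(
            filter(None, (_element_text(e) for e in article.iter("AbstractText")))
        )
        records.append(AbstractRecord(pmid=pmid, title=title, abstract=abstract))
    return records


def write_medline_xml(records: Sequence[AbstractRecord], path: str | Path) -> None:
    """Write records in the same minimal dialect ``read_medline_xml`` accepts."""
    root = ET.Element("PubmedArticleSet")
    for rec in records:
        art = ET.SubElement(root, "PubmedArticle")
        ET.SubElement(art, "PMID").text = rec.pmid
        ET.SubElement(art, "ArticleTitle").text = rec.title
        ET.SubElement(art, "AbstractText").text = rec.abstract
    ET.indent(root)
    Path(path).write_text(ET.tostring(root, encoding="unicode") + "\n")


# Tokens that commonly precede a period without ending a sentence.
_ABBREVIATIONS = frozenset(
    "e.g i.e al fig figs dr mr mrs prof vs cf ca approx resp no st".split()
)

_BOUNDARY = re.compile(r"[.?!](?=\s+[A-Z0-9(])")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting.

    Splits after ``. ? !`` followed by whitespace and a capital/digit, unless
    the preceding token is a known abbreviation. Hyphens, parentheses and
    decimal points never split. Concatenating the output (modulo whitespace)
    reproduces the input; empty input yields an empty list.
    """
    if not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        if m.group(0) == ".":
            prev = re.search(r"([\w.]+)\.$", text[start:end])
            if prev and prev.group(1).casefold().rstrip(".") in _ABBREVIATIONS:
                continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence: str) -> list[str]:
    """Whitespace tokens with surrounding punctuation stripped; empties dropped."""
    out = []
    for raw in sentence.split():
        tok = raw.strip(string.punctuation)
        if tok:
            out.append(tok)
    return out


def select_sentences(
    records: Iterable[AbstractRecord], lexicon: EffectLexicon | Mapping[str, str]
) -> list[SentenceMatch]:
    """Sentences whose tokens include an effect word, one match per matching token.

    A token matches when its case-folded Porter stem is a lexicon key. A
    sentence containing two different effect words yields two matches;
    repeated occurrences of the same surface form yield one.
    """
    entries = lexicon.entries if isinstance(lexicon, EffectLexicon) else dict(lexicon)
    if not entries:
        raise ValueError("effect lexicon is empty")
    matches: list[SentenceMatch] = []
    for record in records:
        for sent_index, sentence in enumerate(split_sentences(record.abstract)):
            seen: set[tuple[str, str]] = set()
            for token in tokenize(sentence):
                token_stem = stem(token)
                key = (token_stem, token.casefold())
                if token_stem in entries and key not in seen:
                    seen.add(key)
                    matches.append(
                        SentenceMatch(
                            pmid=record.pmid,
                            sentence=sentence,
                            effect_surface=token,
                            effect_stem=token_stem,
                            effect_type=entries[token_stem],
                            sent_index=sent_index,
                        )
                    )
    return matches
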