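"""Sentences as link-grammar-style graphs.

A parsed sentence is a graph whose vertices are word tokens and whose edges
are typed links (subject links ``S``, object links ``O``, modifier links
``MV``, noun-compound links ``AN``, ...). Link labels are stored in *reduced*
form — the uppercase primary type with lowercase subscripts stripped, so
``Ss`` and ``Sp`` both reduce to ``S`` — because extraction rules generalize
over subscripts. Links are stored with ``left < right`` token order; a rule's
``+``/``-`` direction is resolved against token positions at traversal time.

The file format here is an interchange contract replacing an external parser:
any real parser can emit it. A small template *toy linker* builds graphs for
fixture sentences of known shape; it is not a parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .stemming import stem

__all__ = [
    "PLACEHOLDERS",
    "ParseToken",
    "ParseLink",
    "ParseGraph",
    "TaggedSentence",
    "LinkageTemplate",
    "ParseFormatError",
    "UnsupportedSentenceError",
    "reduce_label",
    "read_parse_file",
    "write_parse_file",
    "expand_entity",
    "toy_linker",
    "tag_with_template",
]

PLACEHOLDERS = ("@SUBSTANCE", "@SYMPTOM", "@DISEASE", "@BODYPART")

#: Reduced labels followed leftward when expanding an entity head to the full
#: name span (noun-modifier / adjective / proper-name links).
DEFAULT_EXPANSION_LABELS = frozenset({"AN", "A", "G"})


class ParseFormatError(ValueError):
    """Invalid parse file content or link label."""


class UnsupportedSentenceError(ValueError):
    """The toy linker has no template matching the sentence."""


_LABEL_RE = re.compile(r"^([A-Z]+)")


def reduce_label(full_label: str) -> str:
    """Uppercase primary part of a link label: ``Ss`` -> ``S``, ``MVp`` -> ``MV``.

    Trailing lowercase subscripts and wildcard characters are stripped.
    Idempotent; a label with no uppercase prefix is a format error.
    """
    m = _LABEL_RE.match(full_label)
    if not m:
        raise ParseFormatError(f"link label {full_label!r} has no uppercase prefix")
    return m.group(1)


@dataclass(frozen=True)
class ParseToken:
    index: int
    surface: str

    @property
    def stem(self) -> str:
        return stem(self.surface)


@dataclass(frozen=True)
class ParseLink:
    """A link between two tokens, stored with ``left < right``."""

    left: int
    right: int
    full_label: str

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ParseFormatError(
                f"link ({self.left},{self.right}) must have left < right"
            )

    @property
    def reduced_label(self) -> str:
        return reduce_label(self.full_label)


@dataclass(frozen=True)
class ParseGraph:
    sentence_id: str
    tokens: tuple[ParseToken, ...]
    links: frozenset[ParseLink] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ParseFormatError(
                    f"{self.sentence_id}: token indices not consecutive at {i}"
                )
        seen: set[tuple[int, int, str]] = set()
        n = len(self.tokens)
        for link in self.links:
            if link.right >= n:
                raise ParseFormatError(
                    f"{self.sentence_id}: link ({link.left},{link.right},"
                    f"{link.full_label}) references token beyond {n - 1}"
                )
            triple = (link.left, link.right, link.full_label)
            if triple in seen:
                raise ParseFormatError(f"{self.sentence_id}: duplicate link {triple}")
            seen.add(triple)

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)

    def neighbors(self, at: int, label: str, direction: str) -> set[int]:
        """Token indices reachable from ``at`` over one link of reduced ``label``.

        Direction ``-`` looks left (links ending at ``at``), ``+`` looks right.
        """
        if direction not in "+-":
            raise ValueError(f"direction must be '+' or '-', got {direction!r}")
        if not 0 <= at < len(self.tokens):
            raise IndexError(f"token index {at} out of range")
        result: set[int] = set()
        for link in self.links:
            if link.reduced_label != label:
                continue
            if direction == "-" and link.right == at:
                result.add(link.left)
            elif direction == "+" and link.left == at:
                result.add(link.right)
        return result

    def span_text(self, span: tuple[int, int]) -> str:
        start, end = span
        return " ".join(t.surface for t in self.tokens[start : end + 1])


@dataclass(frozen=True)
class TaggedSentence:
    """A training sentence: parse graph plus user-marked effect and concepts.

    ``concept_tags`` maps closed token spans ``(start, end)`` to placeholders
    (@SUBSTANCE, @SYMPTOM, @DISEASE, @BODYPART). Tagged spans must not cover
    the effect token.
    """

    graph: ParseGraph
    effect_index: int
    concept_tags: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        n = len(self.graph.tokens)
        if not 0 <= self.effect_index < n:
            raise ParseFormatError("effect index out of range")
        for (start, end), placeholder in self.concept_tags.items():
            if placeholder not in PLACEHOLDERS:
                raise ParseFormatError(f"unknown placeholder {placeholder!r}")
            if not (0 <= start <= end < n):
                raise ParseFormatError(f"tag span ({start},{end}) out of range")
            if start <= self.effect_index <= end:
                raise ParseFormatError("tagged span overlaps the effect token")


def expand_entity(
    graph: ParseGraph,
    head: int,
    expansion_labels: Iterable[str] = DEFAULT_EXPANSION_LABELS,
) -> tuple[int, int]:
    """Expand an entity head leftward to the full multi-word name.

    Returns the maximal contiguous closed span ``(start, head)`` such that
    each added token is joined to the span by a link whose reduced label is in
    ``expansion_labels`` (noun compounds like "tolfenamic acid"). The span
    always contains ``head``.
    """
    labels = frozenset(expansion_labels)
    if not 0 <= head < len(graph.tokens):
        raise IndexError(f"token index {head} out of range")
    start = head
    grew = True
    while grew and start > 0:
        grew = False
        for link in graph.links:
            if (
                link.left == start - 1
                and start <= link.right <= head
                and link.reduced_label in labels
            ):
                start -= 1
                grew = True
                break
    return (start, head)


# ---------------------------------------------------------------------------
# Parse file interchange format
#
#   # comment
#   S <sentence_id>
#   W <index> <surface>
#   L <left> <right> <full_label>
#   E <index>                      (optional: effect token, training blocks)
#   T <start> <end> @PLACEHOLDER   (optional: concept tag, training blocks)
#   <blank line terminates the block>
# ---------------------------------------------------------------------------


def _finish_block(
    header: str,
    words: list[tuple[int, str]],
    links: list[tuple[int, int, str]],
    effect: int | None,
    tags: list[tuple[int, int, str]],
    where: str,
) -> ParseGraph | TaggedSentence:
    tokens = tuple(ParseToken(i, s) for i, s in sorted(words))
    n = len(tokens)
    for left, right, label in links:
        if not (0 <= left < n and 0 <= right < n):
            raise ParseFormatError(
                f"{where}: link ({left},{right},{label}) out of range for {n} tokens"
            )
    graph = ParseGraph(
        sentence_id=header,
        tokens=tokens,
        links=frozenset(ParseLink(l, r, lab) for l, r, lab in links),
    )
    if effect is None and not tags:
        return graph
    if effect is None:
        raise ParseFormatError(f"{where}: T tags without an E effect line")
    return TaggedSentence(
        graph=graph,
        effect_index=effect,
        concept_tags={(s, e): p for s, e, p in tags},
    )


def read_parse_file(path: str | Path) -> list[ParseGraph | TaggedSentence]:
    """Read parse blocks; blocks with E/T lines become :class:`TaggedSentence`."""
    blocks: list[ParseGraph | TaggedSentence] = []
    header: str | None = None
    words: list[tuple[int, str]] = []
    links: list[tuple[int, int, str]] = []
    effect: int | None = None
    tags: list[tuple[int, int, str]] = []

    def flush(where: str) -> None:
        nonlocal header, words, links, effect, tags
        if header is not None:
            blocks.append(_finish_block(header, words, links, effect, tags, where))
        header, words, links, effect, tags = None, [], [], None, []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        where = f"{path}:{lineno}"
        if not line.strip():
            flush(where)
            continue
        parts = line.split()
        kind = parts[0]
        try:
            if kind == "S" and len(parts) == 2:
                flush(where)
                header = parts[1]
            elif kind == "W" and len(parts) >= 3:
                words.append((int(parts[1]), " ".join(parts[2:])))
            elif kind == "L" and len(parts) == 4:
                links.append((int(parts[1]), int(parts[2]), parts[3]))
            elif kind == "E" and len(parts) == 2:
                effect = int(parts[1])
            elif kind == "T" and len(parts) == 4:
                tags.append((int(parts[1]), int(parts[2]), parts[3]))
            else:
                raise ParseFormatError(f"{where}: unrecognized line {raw!r}")
        except ValueError as exc:
            if isinstance(exc, ParseFormatError):
                raise
            raise ParseFormatError(f"{where}: {exc}") from exc
        if header is None:
            raise ParseFormatError(f"{where}: {kind} line before S header")
    flush(f"{path}:EOF")
    return blocks


def write_parse_file(
    blocks: Sequence[ParseGraph | TaggedSentence], path: str | Path
) -> None:
    """Write blocks in the interchange format (inverse of :func:`read_parse_file`)."""
    lines: list[str] = []
    for block in blocks:
        graph = block.graph if isinstance(block, TaggedSentence) else block
        lines.append(f"S {graph.sentence_id}")
        for tok in graph.tokens:
            lines.append(f"W {tok.index} {tok.surface}")
        for link in sorted(graph.links, key=lambda l: (l.left, l.right, l.full_label)):
            lines.append(f"L {link.left} {link.right} {link.full_label}")
        if isinstance(block, TaggedSentence):
            lines.append(f"E {block.effect_index}")
            for (start, end), placeholder in sorted(block.concept_tags.items()):
                lines.append(f"T {start} {end} {placeholder}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Toy linker: deterministic template graphs for fixture sentences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkageTemplate:
    """A fixed sentence shape with a known linkage.

    ``skeleton`` items are either ``{SLOT}`` names (matching one or more
    tokens) or literal alternations like ``"induces|reduces"``. ``links``
    connect skeleton items by index using each item's head token (the last
    token of a slot span); multi-token slots additionally get internal ``AN``
    links. ``effect_item`` marks the effect word; ``placeholders`` maps slot
    names to concept placeholders for training use.
    """

    name: str
    skeleton: tuple[str, ...]
    links: tuple[tuple[int, int, str], ...]
    effect_item: int
    placeholders: dict[str, str]

    def slot_names(self) -> list[str]:
        return [s[1:-1] for s in self.skeleton if s.startswith("{")]

    def _match(self, tokens: Sequence[str]) -> dict[int, tuple[int, int]] | None:
        """Assign each skeleton item a token span; None if no assignment works."""

        def rec(item: int, pos: int) -> dict[int, tuple[int, int]] | None:
            if item == len(self.skeleton):
                return {} if pos == len(tokens) else None
            spec = self.skeleton[item]
            if spec.startswith("{"):
                max_len = len(tokens) - pos - (len(self.skeleton) - item - 1)
                for width in range(1, max_len + 1):
                    rest = rec(item + 1, pos + width)
                    if rest is not None:
                        return {item: (pos, pos + width - 1), **rest}
                return None
            if pos < len(tokens) and tokens[pos].casefold() in spec.casefold().split("|"):
                rest = rec(item + 1, pos + 1)
                if rest is not None:
                    return {item: (pos, pos), **rest}
            return None

        return rec(0, 0)

    def realize(self, sentence: str, sentence_id: str = "toy") -> ParseGraph | None:
        tokens = sentence.rstrip(" .!?").split()
        if not tokens:
            return None
        spans = self._match(tokens)
        if spans is None:
            return None
        links: set[ParseLink] = set()
        for item, (start, end) in spans.items():
            if self.skeleton[item].startswith("{"):
                for i in range(start, end):
                    links.add(ParseLink(i, i + 1, "AN"))
        for a, b, label in self.links:
            ha, hb = spans[a][1], spans[b][1]
            left, right = min(ha, hb), max(ha, hb)
            links.add(ParseLink(left, right, label))
        return ParseGraph(
            sentence_id=sentence_id,
            tokens=tuple(ParseToken(i, s) for i, s in enumerate(tokens)),
            links=frozenset(links),
        )

    def tag(self, sentence: str, sentence_id: str = "toy") -> TaggedSentence | None:
        graph = self.realize(sentence, sentence_id)
        if graph is None:
            return None
        spans = self._match(list(graph.surfaces))
        assert spans is not None
        effect_index = spans[self.effect_item][1]
        concept_tags: dict[tuple[int, int], str] = {}
        for item, span in spans.items():
            spec = self.skeleton[item]
            if spec.startswith("{"):
                name = spec[1:-1]
                if name in self.placeholders:
                    concept_tags[span] = self.placeholders[name]
        return TaggedSentence(
            graph=graph, effect_index=effect_index, concept_tags=concept_tags
        )


def toy_linker(
    sentence: str,
    templates: Sequence[LinkageTemplate],
    sentence_id: str = "toy",
) -> ParseGraph:
    """Graph for a fixture sentence via the first matching template.

    Deterministic and template-bound; raises
    :class:`UnsupportedSentenceError` for anything else. Not a parser.
    """
    if not sentence.strip():
        raise UnsupportedSentenceError("empty sentence")
    for template in templates:
        graph = template.realize(sentence, sentence_id)
        if graph is not None:
            return graph
    raise UnsupportedSentenceError(f"no template matches: {sentence!r}")


def tag_with_template(
    sentence: str,
    templates: Sequence[LinkageTemplate],
    sentence_id: str = "toy",
) -> TaggedSentence:
    """Tagged training sentence via the first matching template."""
    if not sentence.strip():
        raise UnsupportedSentenceError("empty sentence")
    for template in templates:
        tagged = template.tag(sentence, sentence_id)
        if tagged is not None:
            return tagged
    raise UnsupportedSentenceError(f"no template matches: {sentence!r}")
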