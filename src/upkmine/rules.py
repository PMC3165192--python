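"""Path-rule learning and matching over parse graphs.

An extraction rule is the shortest link path from an effect word to a tagged
concept: an ordered list of steps, each a (reduced link label, direction)
pair, with intermediate words kept as stemmed *node* constraints and the
final step landing on a concept placeholder. ``S- @SUBSTANCE`` reads: from
the effect word, follow one subject link leftward; the token found there
(expanded to its full entity name) is the substance.

Rule satisfaction requires the whole route: every step's link present with
the right label and direction, every node word's stem in place.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .corpus import SentenceMatch
from .parsegraph import (
    PLACEHOLDERS,
    ParseGraph,
    TaggedSentence,
    expand_entity,
)

__all__ = [
    "RuleStep",
    "ExtractionRule",
    "RawExtraction",
    "RuleLearningError",
    "RulebookFormatError",
    "learn_rules",
    "write_rulebook",
    "parse_rulebook",
    "rules_for_stem",
    "match_rule",
    "apply_rulebook",
]

logger = logging.getLogger(__name__)


class RuleLearningError(ValueError):
    """A tagged concept is unreachable from the effect word."""


class RulebookFormatError(ValueError):
    """Malformed rulebook line."""


@dataclass(frozen=True)
class RuleStep:
    """One traversal step: reduced label, direction, optional node-word stem."""

    reduced_label: str
    direction: str
    node_stem: str | None = None

    def __post_init__(self) -> None:
        if not self.reduced_label:
            raise ValueError("empty reduced label")
        if self.direction not in "+-":
            raise ValueError(f"direction must be '+' or '-', got {self.direction!r}")
        if self.node_stem is not None and self.node_stem != self.node_stem.casefold():
            raise ValueError(f"node stem {self.node_stem!r} not case-folded")

    def render(self) -> str:
        text = f"{self.reduced_label}{self.direction}"
        if self.node_stem is not None:
            text += f" ({self.node_stem})"
        return text


@dataclass(frozen=True)
class ExtractionRule:
    effect_stem: str
    steps: tuple[RuleStep, ...]
    placeholder: str

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a rule needs at least one step")
        if self.steps[-1].node_stem is not None:
            raise ValueError("final step lands on the concept and carries no node word")
        if self.placeholder not in PLACEHOLDERS:
            raise ValueError(f"unknown placeholder {self.placeholder!r}")

    def render(self) -> str:
        steps = " ".join(step.render() for step in self.steps)
        return f"{self.effect_stem} :: {steps} {self.placeholder}"


@dataclass
class RawExtraction:
    """Untyped slot bindings for one sentence, before entity recognition."""

    pmid: str
    sentence: str
    effect_surface: str
    effect_stem: str
    slots: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for placeholder, terms in self.slots.items():
            if placeholder not in PLACEHOLDERS:
                raise ValueError(f"unknown placeholder {placeholder!r}")
            if any(not term for term in terms):
                raise ValueError("empty slot term")


def _link_graph(graph: ParseGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(graph.tokens)))
    for link in graph.links:
        if g.has_edge(link.left, link.right):
            g[link.left][link.right]["labels"].add(link.reduced_label)
        else:
            g.add_edge(link.left, link.right, labels={link.reduced_label})
    return g


def _path_to_steps(
    graph: ParseGraph, g: nx.Graph, node_path: Sequence[int]
) -> list[tuple[RuleStep, ...]]:
    """All step sequences realizing a node path (parallel labels fan out)."""
    per_hop: list[list[RuleStep]] = []
    for hop, (u, v) in enumerate(zip(node_path, node_path[1:])):
        direction = "+" if v > u else "-"
        last = hop == len(node_path) - 2
        node_stem = None if last else graph.tokens[v].stem
        labels = sorted(g[u][v]["labels"])
        per_hop.append(
            [RuleStep(label, direction, node_stem) for label in labels]
        )
    return [tuple(combo) for combo in product(*per_hop)]


def _step_sort_key(steps: tuple[RuleStep, ...]):
    return tuple(
        (s.reduced_label, s.direction, s.node_stem or "") for s in steps
    )


def learn_rules(tagged: TaggedSentence) -> set[ExtractionRule]:
    """One rule per tagged concept: the shortest effect-to-concept link path.

    Breadth-first shortest paths; among equal-length paths the step sequence
    that is lexicographically smallest by (reduced label, direction, node
    stem) wins, so learned rulebooks are deterministic. The concept span's
    head is its rightmost token. An unreachable concept raises
    :class:`RuleLearningError`.
    """
    graph = tagged.graph
    g = _link_graph(graph)
    effect_stem = graph.tokens[tagged.effect_index].stem
    rules: set[ExtractionRule] = set()
    for (start, end), placeholder in sorted(tagged.concept_tags.items()):
        head = end
        try:
            node_paths = list(
                nx.all_shortest_paths(g, tagged.effect_index, head)
            )
        except nx.NetworkXNoPath as exc:
            raise RuleLearningError(
                f"{graph.sentence_id}: concept span ({start},{end}) "
                f"{placeholder} unreachable from effect token "
                f"{tagged.effect_index}"
            ) from exc
        candidates: list[tuple[RuleStep, ...]] = []
        for node_path in node_paths:
            candidates.extend(_path_to_steps(graph, g, node_path))
        best = min(candidates, key=_step_sort_key)
        rules.add(ExtractionRule(effect_stem, best, placeholder))
    return rules


# ---------------------------------------------------------------------------
# Rulebook file: `<effect_stem> :: <LABEL><+|-> [(node_stem)] ... @CONCEPT`
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(r"([A-Z]+)([+-])(?:\s+\(([^()\s]+)\))?")


def write_rulebook(rules: Iterable[ExtractionRule], path: str | Path) -> None:
    lines = sorted(rule.render() for rule in rules)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_rule_line(line: str, where: str) -> ExtractionRule:
    if "::" not in line:
        raise RulebookFormatError(f"{where}: missing '::' separator")
    head, _, body = line.partition("::")
    effect_stem = head.strip()
    body = body.strip()
    if not effect_stem:
        raise RulebookFormatError(f"{where}: empty effect stem")
    parts = body.rsplit(None, 1)
    if len(parts) != 2 or parts[1] not in PLACEHOLDERS:
        raise RulebookFormatError(f"{where}: rule must end with a @PLACEHOLDER")
    steps_text, placeholder = parts
    steps: list[RuleStep] = []
    pos = 0
    while pos < len(steps_text):
        m = _STEP_RE.match(steps_text, pos)
        if not m:
            raise RulebookFormatError(
                f"{where}: cannot parse step at {steps_text[pos:]!r}"
            )
        steps.append(RuleStep(m.group(1), m.group(2), m.group(3)))
        pos = m.end()
        while pos < len(steps_text) and steps_text[pos].isspace():
            pos += 1
    if not steps:
        raise RulebookFormatError(f"{where}: rule has no steps")
    try:
        return ExtractionRule(effect_stem, tuple(steps), placeholder)
    except ValueError as exc:
        raise RulebookFormatError(f"{where}: {exc}") from exc


def parse_rulebook(path: str | Path) -> set[ExtractionRule]:
    """Round-trip inverse of :func:`write_rulebook`; ``#`` starts a comment."""
    rules: set[ExtractionRule] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rules.add(_parse_rule_line(line, f"{path}:{lineno}"))
    return rules


def rules_for_stem(
    rulebook: Iterable[ExtractionRule], effect_stem: str
) -> list[ExtractionRule]:
    return sorted(
        (r for r in rulebook if r.effect_stem == effect_stem),
        key=lambda r: (r.placeholder, _step_sort_key(r.steps)),
    )


def match_rule(
    graph: ParseGraph,
    effect_index: int,
    rule: ExtractionRule,
    expansion_labels: Iterable[str] | None = None,
) -> set[tuple[int, int]]:
    """All concept spans bound by traversing the rule from the effect token.

    Every step follows *all* links of its reduced label in its direction
    (set semantics); node-word steps additionally require the landed token's
    stem. Terminal tokens expand to full entity spans. A route that cannot be
    completed yields the empty set.
    """
    if graph.tokens[effect_index].stem != rule.effect_stem:
        raise ValueError(
            f"token {effect_index} stems to "
            f"{graph.tokens[effect_index].stem!r}, rule expects {rule.effect_stem!r}"
        )
    frontier = {effect_index}
    for step in rule.steps:
        reached: set[int] = set()
        for at in frontier:
            for nb in graph.neighbors(at, step.reduced_label, step.direction):
                if step.node_stem is None or graph.tokens[nb].stem == step.node_stem:
                    reached.add(nb)
        if not reached:
            return set()
        frontier = reached
    kwargs = {} if expansion_labels is None else {"expansion_labels": expansion_labels}
    return {expand_entity(graph, head, **kwargs) for head in frontier}


def apply_rulebook(
    graph: ParseGraph,
    match: SentenceMatch,
    rulebook: Iterable[ExtractionRule],
    expansion_labels: Iterable[str] | None = None,
) -> RawExtraction | None:
    """Aggregate the bindings of every rule keyed to the matched effect stem.

    Duplicate spans per placeholder are deduplicated; returns ``None`` when
    no placeholder binds at all.
    """
    effect_indices = [
        tok.index for tok in graph.tokens if tok.stem == match.effect_stem
    ]
    slots: dict[str, set[str]] = {}
    for rule in rules_for_stem(rulebook, match.effect_stem):
        for effect_index in effect_indices:
            for span in match_rule(graph, effect_index, rule, expansion_labels):
                slots.setdefault(rule.placeholder, set()).add(graph.span_text(span))
    if not slots:
        return None
    return RawExtraction(
        pmid=match.pmid,
        sentence=match.sentence,
        effect_surface=match.effect_surface,
        effect_stem=match.effect_stem,
        slots={p: tuple(sorted(terms)) for p, terms in sorted(slots.items())},
    )
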