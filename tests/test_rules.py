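"""Rule learning, rulebook serialization and rule matching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from upkmine.corpus import SentenceMatch
from upkmine.fixtures import TEMPLATES, training_tagged_sentences
from upkmine.parsegraph import TaggedSentence, tag_with_template
from upkmine.rules import (
    ExtractionRule,
    RuleLearningError,
    RulebookFormatError,
    RuleStep,
    apply_rulebook,
    learn_rules,
    match_rule,
    parse_rulebook,
    write_rulebook,
)

from conftest import make_graph


class TestLearnRules:
    def test_adjacent_substance_rule(self, fig_rule_graph):
        """Leftward subject link from the effect lands on the substance head."""
        tagged = TaggedSentence(
            graph=fig_rule_graph, effect_index=2, concept_tags={(0, 1): "@SUBSTANCE"}
        )
        (rule,) = learn_rules(tagged)
        assert rule.effect_stem == "induc"
        assert rule.steps == (RuleStep("S", "-"),)
        assert rule.placeholder == "@SUBSTANCE"
        assert rule.render() == "induc :: S- @SUBSTANCE"

    def test_two_edge_path_records_node_word(self):
        g = make_graph(
            "g", ["inducer", "of", "apoptosis"], [(0, 1, "Mp"), (1, 2, "Js")]
        )
        tagged = TaggedSentence(graph=g, effect_index=0, concept_tags={(2, 2): "@SYMPTOM"})
        (rule,) = learn_rules(tagged)
        assert rule.steps == (RuleStep("M", "+", "of"), RuleStep("J", "+"))

    def test_disconnected_concept_is_error(self):
        g = make_graph("g", ["induces", "x", "orphan"], [(0, 1, "Os")])
        tagged = TaggedSentence(graph=g, effect_index=0, concept_tags={(2, 2): "@DISEASE"})
        with pytest.raises(RuleLearningError):
            learn_rules(tagged)

    def test_tie_break_is_deterministic(self):
        # two parallel equal-length paths: labels A.. vs B..; A must win
        g = make_graph("g", ["induces", "target"], [(0, 1, "Bs"), (0, 1, "As")])
        tagged = TaggedSentence(graph=g, effect_index=0, concept_tags={(1, 1): "@SYMPTOM"})
        (rule,) = learn_rules(tagged)
        assert rule.steps == (RuleStep("A", "+"),)

    def test_rule_paths_are_shortest(self):
        """A direct link must beat a two-edge detour to the same concept."""
        g = make_graph(
            "g",
            ["drug", "induces", "of", "apoptosis"],
            [(0, 1, "Ss"), (1, 2, "Mp"), (2, 3, "Js"), (1, 3, "Os")],
        )
        tagged = TaggedSentence(graph=g, effect_index=1, concept_tags={(3, 3): "@SYMPTOM"})
        (rule,) = learn_rules(tagged)
        assert len(rule.steps) == 1
        assert rule.steps == (RuleStep("O", "+"),)


class TestRulebook:
    def test_rendered_line_format(self, fig_rule_graph):
        tagged = TaggedSentence(
            graph=fig_rule_graph, effect_index=2, concept_tags={(0, 1): "@SUBSTANCE"}
        )
        (rule,) = learn_rules(tagged)
        assert rule.render() == "induc :: S- @SUBSTANCE"

    def test_empty_set_round_trips(self, tmp_path):
        path = tmp_path / "rules.txt"
        write_rulebook(set(), path)
        assert parse_rulebook(path) == set()

    steps_strategy = st.lists(
        st.builds(
            RuleStep,
            reduced_label=st.from_regex(r"[A-Z]{1,2}", fullmatch=True),
            direction=st.sampled_from("+-"),
            node_stem=st.from_regex(r"[a-z]{1,6}", fullmatch=True),
        ),
        min_size=0,
        max_size=3,
    )

    @given(
        rules=st.sets(
            st.builds(
                ExtractionRule,
                effect_stem=st.from_regex(r"[a-z]{2,8}", fullmatch=True),
                steps=steps_strategy.map(
                    lambda steps: tuple(steps)
                    + (RuleStep("J", "+"),)  # terminal step carries no node word
                ),
                placeholder=st.sampled_from(
                    ["@SUBSTANCE", "@SYMPTOM", "@DISEASE", "@BODYPART"]
                ),
            ),
            max_size=6,
        )
    )
    def test_round_trip_identity(self, rules, tmp_path_factory):
        path = tmp_path_factory.mktemp("rb") / "rules.txt"
        write_rulebook(rules, path)
        assert parse_rulebook(path) == rules

    @pytest.mark.parametrize(
        "line",
        [
            "no separator here",
            "induc :: S- @NOWHERE",
            "induc :: @SUBSTANCE",
            "induc :: s- @SUBSTANCE",
        ],
    )
    def test_malformed_lines_name_position(self, tmp_path, line):
        path = tmp_path / "bad.txt"
        path.write_text(line + "\n")
        with pytest.raises(RulebookFormatError, match="bad.txt:1"):
            parse_rulebook(path)


class TestMatchRule:
    def test_substance_binding_with_expansion(self, fig_rule_graph):
        rule = ExtractionRule("induc", (RuleStep("S", "-"),), "@SUBSTANCE")
        spans = match_rule(fig_rule_graph, 2, rule)
        assert spans == {(0, 1)}
        assert fig_rule_graph.span_text((0, 1)) == "tolfenamic acid"

    def test_direction_mismatch_yields_empty(self):
        g = make_graph("g", ["induces", "acid"], [(0, 1, "Ss")])  # rightward S only
        rule = ExtractionRule("induc", (RuleStep("S", "-"),), "@SUBSTANCE")
        assert match_rule(g, 0, rule) == set()

    def test_two_leftward_links_give_two_bindings(self):
        g = make_graph("g", ["fisetin", "wogonin", "induces"], [(0, 2, "Ss"), (1, 2, "Sp")])
        rule = ExtractionRule("induc", (RuleStep("S", "-"),), "@SUBSTANCE")
        assert match_rule(g, 2, rule) == {(0, 0), (1, 1)}

    def test_node_word_constraint_enforced(self):
        g = make_graph("g", ["inducer", "by", "stress"], [(0, 1, "Mp"), (1, 2, "Js")])
        rule = ExtractionRule(
            "induc", (RuleStep("M", "+", "of"), RuleStep("J", "+")), "@SYMPTOM"
        )
        assert match_rule(g, 0, rule) == set()

    def test_effect_stem_precondition(self, fig_rule_graph):
        rule = ExtractionRule("reduc", (RuleStep("S", "-"),), "@SUBSTANCE")
        with pytest.raises(ValueError):
            match_rule(fig_rule_graph, 2, rule)


class TestApplyRulebook:
    def test_tolfenamic_sentence_binds_three_slots(self):
        sentence = "Tolfenamic acid induces Sp protein degradation in cancer cell lines."
        graph = toy = tag_with_template(sentence, TEMPLATES).graph
        rulebook = set()
        for tagged in training_tagged_sentences():
            from upkmine.rules import learn_rules as lr

            rulebook |= lr(tagged)
        match = SentenceMatch(
            pmid="19258429",
            sentence=sentence,
            effect_surface="induces",
            effect_stem="induc",
            effect_type="Increase",
        )
        raw = apply_rulebook(graph, match, rulebook)
        assert raw is not None
        assert raw.slots["@SUBSTANCE"] == ("Tolfenamic acid",)
        assert raw.slots["@SYMPTOM"] == ("Sp protein degradation",)
        assert raw.slots["@BODYPART"] == ("cancer cell lines",)

    def test_no_rule_fires_returns_none(self, fig_rule_graph):
        match = SentenceMatch("1", "x", "induces", "induc", "Increase")
        rule = ExtractionRule("induc", (RuleStep("MV", "+"),), "@BODYPART")
        assert apply_rulebook(fig_rule_graph, match, {rule}) is None

    def test_duplicate_bindings_deduplicated(self, fig_rule_graph):
        match = SentenceMatch("1", "x", "induces", "induc", "Increase")
        rules = {
            ExtractionRule("induc", (RuleStep("S", "-"),), "@SUBSTANCE"),
            # same landing spot through the same link, different rule object
            ExtractionRule("induc", (RuleStep("S", "-", None),), "@SUBSTANCE"),
        }
        raw = apply_rulebook(fig_rule_graph, match, rules)
        assert raw.slots["@SUBSTANCE"] == ("tolfenamic acid",)


class TestLearnThenMatchClosure:
    @pytest.mark.parametrize("index", range(8))
    def test_rules_rebind_their_training_spans(self, index):
        """Matching the rules learned from a tagged sentence against its own
        graph recovers exactly the tagged concept spans."""
        tagged = training_tagged_sentences()[index]
        graph = tagged.graph
        for rule in learn_rules(tagged):
            spans = match_rule(graph, tagged.effect_index, rule)
            expected = {
                span
                for span, placeholder in tagged.concept_tags.items()
                if placeholder == rule.placeholder
            }
            assert spans == expected
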