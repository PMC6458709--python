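"""Word rules, grammar rules, specialization, KB validation/serialization."""

import logging

import pytest

from moonstone import grammar as gr
from moonstone import tsl
from moonstone.chartparser import Annotation, build_grammar_hosts
from moonstone.kb import DATA_DIR, load_kb_dir


def ann(constant, toks, negated=False, semantic_type=None, children=(), rule_name=""):
    toks = frozenset(toks)
    return Annotation(
        start=min(toks) * 10,
        end=max(toks) * 10 + 9,
        token_indices=toks,
        summary_constant=constant,
        semantic_type=semantic_type,
        negated=negated,
        children=tuple(children),
        rule_name=rule_name,
    )


class TestWordRules:
    def test_spouse_rule_phrases(self):
        (rule,) = gr.load_word_rules(
            '(defwords :SPOUSE: <FRIEND_FAMILY> "husband" "wife" "significant other")'
        )
        assert rule.output_constant == ":SPOUSE:"
        assert rule.output_type == "<FRIEND_FAMILY>"
        assert "significant other" in rule.phrases

    def test_duplicate_phrase_across_rules_warns_but_keeps_both(self, caplog):
        text = '(defwords :A: "shared")\n(defwords :B: "shared")'
        with caplog.at_level(logging.WARNING):
            rules = gr.load_word_rules(text)
        assert len(rules) == 2
        assert any("shared" in r.message for r in caplog.records)

    def test_empty_file(self):
        assert gr.load_word_rules("") == []

    def test_empty_phrase_list_rejected(self):
        with pytest.raises(gr.KBLoadError):
            gr.load_word_rules("(defwords :A:)")


HIER = tsl.load_type_hierarchy(
    """
(deftype <ENTITY>)
(deftype <PERSON> <ENTITY>)
(deftype <FRIEND_FAMILY> <PERSON>)
(deftype <ACTION> <ENTITY>)
(deftype <SOCIAL_SUPPORT> <ENTITY>)
(defconstants <PERSON> :PATIENT:)
(defconstants <FRIEND_FAMILY> :SPOUSE:)
(defconstants <ACTION> :PROVISION_OF_CARE:)
(defconstants <SOCIAL_SUPPORT> :POSSIBLE_SUPPORT: :HAVE_SUPPORT:)
"""
)

SUPPORT_RULE_TEXT = """
(defrule support-interaction
  (pattern <FRIEND_FAMILY> :PROVISION_OF_CARE: :PATIENT:)
  (tests (notneg ?2))
  (result :POSSIBLE_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9)
  (window 10))
"""


class TestGrammarRules:
    def test_support_rule_parsed(self):
        (rule,) = gr.load_grammar_rules(SUPPORT_RULE_TEXT, HIER)
        assert rule.pattern == ("<FRIEND_FAMILY>", ":PROVISION_OF_CARE:", ":PATIENT:")
        assert rule.result_constant == ":POSSIBLE_SUPPORT:"
        assert rule.tests == (tsl.read_expression("(notneg ?2)"),)
        assert not rule.ordered and rule.window == 10

    def test_out_of_range_positional_test_rejected(self):
        bad = SUPPORT_RULE_TEXT.replace("(notneg ?2)", "(notneg ?9)")
        with pytest.raises(gr.KBLoadError, match="position"):
            gr.load_grammar_rules(bad, HIER)

    def test_unknown_symbol_names_the_rule(self):
        bad = SUPPORT_RULE_TEXT.replace(":PATIENT:", ":UNDECLARED:")
        with pytest.raises(gr.KBLoadError, match="support-interaction"):
            gr.load_grammar_rules(bad, HIER)

    def test_empty_file(self):
        assert gr.load_grammar_rules("", HIER) == []


class TestMatchElement:
    @pytest.mark.parametrize(
        "element, constant, expected",
        [
            ("<PERSON>", ":SPOUSE:", True),
            (":PATIENT:", ":PATIENT:", True),
            (":PATIENT:", ":SPOUSE:", False),
            ("<FRIEND_FAMILY>", ":PATIENT:", False),
        ],
    )
    def test_constant_and_type_elements(self, element, constant, expected):
        assert gr.match_element(element, ann(constant, {0}), HIER) is expected


class TestEvaluateTests:
    def setup_method(self):
        (self.rule,) = gr.load_grammar_rules(SUPPORT_RULE_TEXT, HIER)
        self.hosts = build_grammar_hosts()

    def test_negated_care_phrase_blocks(self):
        matched = [
            ann(":SPOUSE:", {6}),
            ann(":PROVISION_OF_CARE:", {3}, negated=True),
            ann(":PATIENT:", {0}),
        ]
        assert not gr.evaluate_tests(self.rule, matched, self.hosts)

    def test_non_negated_match_passes(self):
        matched = [
            ann(":SPOUSE:", {0}),
            ann(":PROVISION_OF_CARE:", {1}),
            ann(":PATIENT:", {3}),
        ]
        assert gr.evaluate_tests(self.rule, matched, self.hosts)

    def test_rule_without_tests_passes(self):
        rule = gr.GrammarRule("r", (":PATIENT:",), result_constant=":HAVE_SUPPORT:")
        assert gr.evaluate_tests(rule, [ann(":PATIENT:", {0})], self.hosts)

    def test_unbound_host_relation_errors(self):
        rule = gr.GrammarRule(
            "r",
            (":PATIENT:",),
            tests=(tsl.read_expression("(mystery ?1)"),),
            result_constant=":HAVE_SUPPORT:",
        )
        with pytest.raises(tsl.TSLError):
            gr.evaluate_tests(rule, [ann(":PATIENT:", {0})], self.hosts)


class TestSpecializeRule:
    ABSTRACT = gr.GrammarRule(
        "person-action-person",
        ("<PERSON>", "<ACTION>", "<PERSON>"),
        tests=(tsl.read_expression("(notneg ?2)"),),
    )

    def _tree(self):
        children = [
            ann(":SPOUSE:", {0}),
            ann(":PROVISION_OF_CARE:", {1}),
            ann(":PATIENT:", {2}),
        ]
        return ann(
            ":ABSTRACT_MATCH:", {0, 1, 2}, children=children, rule_name="person-action-person"
        )

    def test_pattern_from_tree_constants(self):
        rule = gr.specialize_rule(self.ABSTRACT, self._tree(), ":HAVE_SUPPORT:", HIER)
        assert rule.pattern == (":SPOUSE:", ":PROVISION_OF_CARE:", ":PATIENT:")
        assert rule.result_constant == ":HAVE_SUPPORT:"
        assert rule.tests == self.ABSTRACT.tests
        assert rule.weight == gr.DEFAULT_RULE_WEIGHT

    def test_undeclared_target_rejected(self):
        with pytest.raises(gr.KBLoadError):
            gr.specialize_rule(self.ABSTRACT, self._tree(), ":NOT_A_CONSTANT:", HIER)

    def test_idempotent(self):
        tree = self._tree()
        r1 = gr.specialize_rule(self.ABSTRACT, tree, ":HAVE_SUPPORT:", HIER)
        r2 = gr.specialize_rule(self.ABSTRACT, tree, ":HAVE_SUPPORT:", HIER)
        assert r1 == r2

    def test_foreign_tree_rejected(self):
        tree = self._tree()
        tree.rule_name = "some-other-rule"
        with pytest.raises(ValueError):
            gr.specialize_rule(self.ABSTRACT, tree, ":HAVE_SUPPORT:", HIER)

    def test_specialized_rule_passes_validation(self, kb):
        abstract = next(r for r in kb.abstract_rules if r.name == "person-action-person")
        children = [
            ann(":SPOUSE:", {0}),
            ann(":PROVISION_OF_CARE:", {1}),
            ann(":PATIENT:", {2}),
        ]
        tree = ann(":ABSTRACT_MATCH:", {0, 1, 2}, children=children, rule_name=abstract.name)
        rule = gr.specialize_rule(abstract, tree, ":HAVE_SUPPORT:", kb.hierarchy)
        kb_copy = gr.KnowledgeBase(
            hierarchy=kb.hierarchy,
            word_rules=kb.word_rules,
            grammar_rules=kb.grammar_rules + [rule],
            abstract_rules=kb.abstract_rules,
            inference_rules=kb.inference_rules,
            template_mappings=kb.template_mappings,
            target_concepts=kb.target_concepts,
        )
        assert gr.validate_kb(kb_copy).ok


class TestValidateKB:
    def test_undefined_result_constant_is_a_finding(self, kb):
        rule = gr.GrammarRule("bad", (":PATIENT:",), result_constant=":UNDEFINED:")
        broken = gr.KnowledgeBase(
            hierarchy=kb.hierarchy,
            grammar_rules=[rule],
            target_concepts=kb.target_concepts,
        )
        report = gr.validate_kb(broken)
        assert any(f.kind == "undeclared-symbol" for f in report.findings)

    def test_cyclic_hierarchy_is_a_finding(self):
        h = tsl.TypeHierarchy()
        h.parents = {"<A>": {"<B>"}, "<B>": {"<A>"}}  # bypass loader checks
        report = gr.validate_kb(gr.KnowledgeBase(hierarchy=h))
        assert any(f.kind == "hierarchy-cycle" for f in report.findings)

    def test_unconsumed_non_target_rule_is_a_finding(self, kb):
        rule = gr.GrammarRule("dangling", (":PATIENT:",), result_constant=":HOME:")
        broken = gr.KnowledgeBase(
            hierarchy=kb.hierarchy,
            grammar_rules=[rule],
            target_concepts=kb.target_concepts,
        )
        report = gr.validate_kb(broken)
        assert any(f.kind == "unreachable-rule" for f in report.findings)


class TestSerializeRoundTrip:
    def test_kb_survives_serialize_reload(self, kb, tmp_path):
        files = gr.serialize_kb(kb)
        for name, text in files.items():
            (tmp_path / name).write_text(text)
        reloaded = load_kb_dir(tmp_path)
        assert reloaded.word_rules == kb.word_rules
        assert reloaded.grammar_rules == kb.grammar_rules
        assert reloaded.abstract_rules == kb.abstract_rules
        assert reloaded.inference_rules == kb.inference_rules
        assert reloaded.template_mappings == kb.template_mappings
        assert reloaded.target_concepts == kb.target_concepts
        assert reloaded.negation_pre_triggers == kb.negation_pre_triggers
        assert reloaded.negation_post_triggers == kb.negation_post_triggers
        assert reloaded.hierarchy.parents == kb.hierarchy.parents
        assert reloaded.hierarchy.constant_types == kb.hierarchy.constant_types
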