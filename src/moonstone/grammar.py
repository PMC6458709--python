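"""Semantic grammar: word rules, grammar rules, knowledge-base container.

The grammar is *semantic*: its categories are domain concepts (``:SPOUSE:``,
``:PROVISION_OF_CARE:``, ``<PERSON>``) rather than syntactic parts of
speech.  A word rule maps one or more surface phrases to a normalizing
object constant; a grammar rule matches a combination of annotations whose
summary constants or semantic types fit its pattern, subject to validation
tests written in TSL over positional variables (``?1`` binds the annotation
matched by the first pattern element, and so on).

Rule files use a small S-expression dialect:

``(defwords :SPOUSE: <FRIEND_FAMILY> "husband" "wife" ...)``
    phrases normalized to a constant, with an optional semantic type;

``(defrule name (pattern e1 e2 ...) (tests t ...) (result :C: <T>)
(interp p ...) (weight w) (ordered bool) (window n))``
    a grammar rule; ``tests``/``interp``/``weight``/``ordered``/``window``
    are optional;

``(defabstract name (pattern <T1> <T2> ...) ...)``
    a domain-neutral abstract rule (no result constant) used by the
    training operation :func:`specialize_rule`;

``(definfer name (if antecedent) (then consequent))``
    a TSL inference rule;

``(deftemplate "label" :AFFIRMED_C: :NEGATED_C:)``
    maps a template field label to the constant asserted when the field is
    affirmed / negated (``nil`` for no mapping);

``(deftarget :C: group "Class label")``
    declares a task-relevant target concept and its output class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import tsl
from .tsl import (
    Compound,
    Expression,
    InferenceRule,
    ObjectConstant,
    Symbol,
    TypeHierarchy,
    TypeName,
    Variable,
    to_sexpr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KBLoadError",
    "WordRule",
    "GrammarRule",
    "TemplateMapping",
    "TargetConcept",
    "KnowledgeBase",
    "ValidationFinding",
    "ValidationReport",
    "load_word_rules",
    "load_grammar_rules",
    "load_inference_rules",
    "load_templates_and_targets",
    "match_element",
    "evaluate_tests",
    "specialize_rule",
    "validate_kb",
    "serialize_kb",
    "DEFAULT_RULE_WEIGHT",
    "DEFAULT_WINDOW",
]

DEFAULT_RULE_WEIGHT = 0.5  # weight given to newly specialized rules
DEFAULT_WINDOW = 10  # max tokens a match may cover ("close proximity")


class KBLoadError(Exception):
    """A knowledge-base file could not be loaded."""


@dataclass(frozen=True)
class WordRule:
    phrases: tuple[str, ...]  # normalized, possibly multi-word
    output_constant: str
    output_type: Optional[str] = None
    weight: float = 1.0

    def __post_init__(self):
        if not self.phrases:
            raise KBLoadError(f"word rule for {self.output_constant} has no phrases")


@dataclass(frozen=True)
class GrammarRule:
    name: str
    pattern: tuple[str, ...]  # object constants and/or type names
    tests: tuple[Expression, ...] = ()
    result_constant: Optional[str] = None  # None for abstract rules
    result_type: Optional[str] = None
    interpretation: tuple[Expression, ...] = ()
    weight: float = 0.9
    ordered: bool = False
    window: int = DEFAULT_WINDOW

    def __post_init__(self):
        if not self.pattern:
            raise KBLoadError(f"rule {self.name}: empty pattern")
        if not (0.0 <= self.weight <= 1.0):
            raise KBLoadError(f"rule {self.name}: weight {self.weight} outside [0, 1]")
        for t in self.tests:
            for v in tsl.variables_of(t):
                if v.is_positional and not (1 <= v.position <= len(self.pattern)):
                    raise KBLoadError(
                        f"rule {self.name}: test {to_sexpr(t)} references position "
                        f"{v.position} but the pattern has {len(self.pattern)} elements"
                    )

    @property
    def is_abstract(self) -> bool:
        return self.result_constant is None


@dataclass(frozen=True)
class TemplateMapping:
    label: str  # normalized (lowercase) field label
    affirmed_constant: Optional[str]
    negated_constant: Optional[str]


@dataclass(frozen=True)
class TargetConcept:
    constant: str
    variable_group: str  # housing | living_alone | social_support
    class_label: str


@dataclass
class KnowledgeBase:
    hierarchy: TypeHierarchy
    word_rules: list = field(default_factory=list)
    grammar_rules: list = field(default_factory=list)  # concrete rules only
    abstract_rules: list = field(default_factory=list)
    inference_rules: list = field(default_factory=list)
    negation_pre_triggers: tuple = ()
    negation_post_triggers: tuple = ()
    template_mappings: list = field(default_factory=list)
    target_concepts: list = field(default_factory=list)
    header_lexicon: tuple = ()
    version: str = "0"

    def class_of(self, constant: str) -> Optional[str]:
        for t in self.target_concepts:
            if t.constant == constant:
                return t.class_label
        return None

    def group_of_class(self, class_label: str) -> Optional[str]:
        for t in self.target_concepts:
            if t.class_label == class_label:
                return t.variable_group
        return None

    @property
    def class_labels(self) -> list:
        return [t.class_label for t in self.target_concepts]


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def _phrase_strings(args) -> list[str]:
    out = []
    for a in args:
        if isinstance(a, Symbol):
            out.append(" ".join(a.name.lower().split()))
        else:
            raise KBLoadError(f"expected a phrase string, got {to_sexpr(a)}")
    return out


def load_word_rules(text: str) -> list[WordRule]:
    """Parse ``defwords`` forms; duplicate phrases across rules are retained
    with a warning (ambiguity is resolved downstream by longest match and
    scoring)."""
    rules: list[WordRule] = []
    seen: dict[str, str] = {}
    for form in tsl.read_all(text):
        if not isinstance(form, Compound) or form.relation != "defwords":
            raise KBLoadError(f"unexpected form in word-rule file: {to_sexpr(form)}")
        args = list(form.args)
        if not args or not isinstance(args[0], ObjectConstant):
            raise KBLoadError(f"defwords needs an output constant: {to_sexpr(form)}")
        constant = args[0].name
        args = args[1:]
        out_type = None
        if args and isinstance(args[0], TypeName):
            out_type = args[0].name
            args = args[1:]
        phrases = _phrase_strings(args)
        if not phrases:
            raise KBLoadError(f"defwords {constant}: empty phrase list")
        for p in phrases:
            if p in seen and seen[p] != constant:
                logger.warning("phrase %r maps to both %s and %s", p, seen[p], constant)
            seen[p] = constant
        rules.append(WordRule(tuple(phrases), constant, out_type))
    return rules


def _rule_sections(form: Compound) -> dict:
    sections: dict[str, list] = {}
    for part in form.args[:]:
        if not isinstance(part, Compound):
            raise KBLoadError(f"bad clause in rule: {to_sexpr(part)}")
        sections[part.relation] = list(part.args)
    return sections


def _element_name(e: Expression, rule_name: str) -> str:
    if isinstance(e, (ObjectConstant, TypeName)):
        return e.name
    raise KBLoadError(f"rule {rule_name}: pattern element {to_sexpr(e)} must be a constant or type")


def _parse_defrule(form: Compound, hierarchy: Optional[TypeHierarchy], abstract: bool) -> GrammarRule:
    if not form.args or not isinstance(form.args[0], Symbol):
        raise KBLoadError(f"rule needs a name: {to_sexpr(form)}")
    name = form.args[0].name
    sections = _rule_sections(Compound(form.relation, form.args[1:]))
    if "pattern" not in sections:
        raise KBLoadError(f"rule {name}: missing (pattern ...)")
    pattern = tuple(_element_name(e, name) for e in sections["pattern"])
    tests = tuple(sections.get("tests", ()))
    interp = tuple(sections.get("interp", ()))
    result_constant = result_type = None
    if not abstract:
        res = sections.get("result")
        if not res or not isinstance(res[0], ObjectConstant):
            raise KBLoadError(f"rule {name}: missing or bad (result :C: [<T>])")
        result_constant = res[0].name
        if len(res) > 1:
            if not isinstance(res[1], TypeName):
                raise KBLoadError(f"rule {name}: result type must be a <TYPE>")
            result_type = res[1].name
    weight = float(sections["weight"][0].name) if "weight" in sections else 0.9
    ordered = (
        sections["ordered"][0].name.lower() in ("true", "t", "yes")
        if "ordered" in sections
        else False
    )
    window = int(sections["window"][0].name) if "window" in sections else DEFAULT_WINDOW
    rule = GrammarRule(
        name=name,
        pattern=pattern,
        tests=tests,
        result_constant=result_constant,
        result_type=result_type,
        interpretation=interp,
        weight=weight,
        ordered=ordered,
        window=window,
    )
    if hierarchy is not None:
        _resolve_rule(rule, hierarchy)
    return rule


def _resolve_rule(rule: GrammarRule, hierarchy: TypeHierarchy) -> None:
    for e in rule.pattern:
        if e.startswith("<"):
            if e not in hierarchy.types:
                raise KBLoadError(f"rule {rule.name}: unknown type {e} in pattern")
        elif e not in hierarchy.constants:
            raise KBLoadError(f"rule {rule.name}: unknown constant {e} in pattern")
    if rule.result_constant is not None and rule.result_constant not in hierarchy.constants:
        raise KBLoadError(f"rule {rule.name}: unknown result constant {rule.result_constant}")


def load_grammar_rules(text: str, hierarchy: Optional[TypeHierarchy] = None) -> list[GrammarRule]:
    """Parse ``defrule`` and ``defabstract`` forms, resolving every symbol
    against *hierarchy* when one is given."""
    rules: list[GrammarRule] = []
    for form in tsl.read_all(text):
        if not isinstance(form, Compound) or form.relation not in ("defrule", "defabstract"):
            raise KBLoadError(f"unexpected form in grammar file: {to_sexpr(form)}")
        rules.append(_parse_defrule(form, hierarchy, abstract=form.relation == "defabstract"))
    return rules


def load_inference_rules(text: str) -> list[InferenceRule]:
    rules: list[InferenceRule] = []
    for form in tsl.read_all(text):
        if not isinstance(form, Compound) or form.relation != "definfer":
            raise KBLoadError(f"unexpected form in inference file: {to_sexpr(form)}")
        if len(form.args) != 3 or not isinstance(form.args[0], Symbol):
            raise KBLoadError(f"definfer needs (definfer name (if ...) (then ...)): {to_sexpr(form)}")
        name, ante, cons = form.args
        if not (isinstance(ante, Compound) and ante.relation == "if" and len(ante.args) == 1):
            raise KBLoadError(f"rule {name.name}: bad (if ...) clause")
        if not (isinstance(cons, Compound) and cons.relation == "then" and len(cons.args) == 1):
            raise KBLoadError(f"rule {name.name}: bad (then ...) clause")
        rules.append(InferenceRule(name.name, ante.args[0], cons.args[0]))
    return rules


def load_templates_and_targets(text: str):
    """Parse ``deftemplate`` and ``deftarget`` forms."""
    templates: list[TemplateMapping] = []
    targets: list[TargetConcept] = []
    for form in tsl.read_all(text):
        if not isinstance(form, Compound):
            raise KBLoadError(f"unexpected form in template file: {to_sexpr(form)}")
        if form.relation == "deftemplate":
            if len(form.args) != 3 or not isinstance(form.args[0], Symbol):
                raise KBLoadError(f"bad deftemplate: {to_sexpr(form)}")
            label = form.args[0].name.lower()

            def const_or_none(a):
                if isinstance(a, Symbol) and a.name == "nil":
                    return None
                if isinstance(a, ObjectConstant):
                    return a.name
                raise KBLoadError(f"bad deftemplate constant: {to_sexpr(a)}")

            templates.append(
                TemplateMapping(label, const_or_none(form.args[1]), const_or_none(form.args[2]))
            )
        elif form.relation == "deftarget":
            if (
                len(form.args) != 3
                or not isinstance(form.args[0], ObjectConstant)
                or not isinstance(form.args[1], Symbol)
                or not isinstance(form.args[2], Symbol)
            ):
                raise KBLoadError(f"bad deftarget: {to_sexpr(form)}")
            targets.append(
                TargetConcept(form.args[0].name, form.args[1].name, form.args[2].name)
            )
        else:
            raise KBLoadError(f"unknown form ({form.relation} ...) in template file")
    return templates, targets


# ---------------------------------------------------------------------------
# Matching and validation-test evaluation
# ---------------------------------------------------------------------------


def match_element(element: str, annotation, hierarchy: TypeHierarchy) -> bool:
    """Does *annotation* fit a rule pattern *element*?

    A constant element matches an equal summary constant; a type element
    matches via subsumption of the annotation's summary constant (or, if
    the constant is undeclared, its semantic type).
    """
    if element.startswith(":"):
        return annotation.summary_constant == element
    c = annotation.summary_constant
    if c in hierarchy.constants:
        return hierarchy.subsumes(element, c)
    if annotation.semantic_type and annotation.semantic_type in hierarchy.types:
        return hierarchy.subsumes(element, annotation.semantic_type)
    return False


def evaluate_tests(rule: GrammarRule, matched, hosts: tsl.HostRegistry) -> bool:
    """Evaluate a rule's validation tests with ``?N`` bound to the N-th
    matched annotation.  Non-positional constants pass through unchanged."""
    if len(matched) != len(rule.pattern):
        raise ValueError(
            f"rule {rule.name}: {len(matched)} matched annotations for a "
            f"{len(rule.pattern)}-element pattern"
        )
    for test in rule.tests:
        if not _eval_test(test, matched, hosts):
            return False
    return True


def _eval_test(test: Expression, matched, hosts: tsl.HostRegistry) -> bool:
    if isinstance(test, tsl.And):
        return all(_eval_test(a, matched, hosts) for a in test.args)
    if isinstance(test, tsl.Or):
        return any(_eval_test(a, matched, hosts) for a in test.args)
    if isinstance(test, tsl.Not):
        return not _eval_test(test.arg, matched, hosts)
    if isinstance(test, Compound):
        if not hosts.is_bound(test.relation):
            raise tsl.TSLError(f"validation test uses unbound host relation {test.relation!r}")
        args = []
        for a in test.args:
            if isinstance(a, Variable) and a.is_positional:
                args.append(matched[a.position - 1])
            elif isinstance(a, (ObjectConstant, TypeName, Symbol)):
                args.append(a.name if not isinstance(a, Symbol) else a.name)
            else:
                raise tsl.TSLError(f"unsupported test argument {to_sexpr(a)}")
        return hosts.call(test.relation, args)
    raise tsl.TSLError(f"unsupported test expression {to_sexpr(test)}")


# ---------------------------------------------------------------------------
# Training: rule specialization
# ---------------------------------------------------------------------------


def specialize_rule(
    abstract: GrammarRule,
    tree,
    target_constant: str,
    hierarchy: TypeHierarchy,
    weight: float = DEFAULT_RULE_WEIGHT,
) -> GrammarRule:
    """Specialize an abstract, domain-neutral rule into a task rule.

    *tree* must be an annotation produced by *abstract*; the new rule's
    pattern is the sequence of its children's summary constants, its result
    is *target_constant*, and the abstract rule's validation tests are
    inherited.  Deterministic, hence idempotent.
    """
    if not abstract.is_abstract:
        raise ValueError(f"rule {abstract.name} is not abstract")
    if tree.rule_name != abstract.name:
        raise ValueError(
            f"parse tree was produced by rule {tree.rule_name!r}, not {abstract.name!r}"
        )
    if target_constant not in hierarchy.constants:
        raise KBLoadError(f"target constant {target_constant} is not declared in the hierarchy")
    if len(tree.children) != len(abstract.pattern):
        raise ValueError("parse tree arity does not match the abstract pattern")
    pattern = tuple(child.summary_constant for child in tree.children)
    return GrammarRule(
        name=f"{abstract.name}~{target_constant.strip(':').lower()}",
        pattern=pattern,
        tests=abstract.tests,
        result_constant=target_constant,
        result_type=abstract.result_type,
        interpretation=abstract.interpretation,
        weight=weight,
        ordered=abstract.ordered,
        window=abstract.window,
    )


# ---------------------------------------------------------------------------
# KB validation and serialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationFinding:
    kind: str  # undeclared-symbol | unreachable-rule | hierarchy-cycle | bad-target-partition
    message: str


@dataclass
class ValidationReport:
    findings: list

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "KB valid: no findings"
        return "\n".join(f"[{f.kind}] {f.message}" for f in self.findings)


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Static checks: undeclared symbols, cycles, unreachable rules.

    A rule counts as reachable when its result constant is a target
    concept, appears in another rule's pattern, or the rule attaches
    interpretation predicates (which feed the inference engine).
    """
    findings: list[ValidationFinding] = []
    h = kb.hierarchy
    # cycles: re-walk parent edges
    for t in h.types:
        try:
            h.ancestors(t)
            h._check_acyclic(t)
        except tsl.HierarchyError as e:
            findings.append(ValidationFinding("hierarchy-cycle", str(e)))
    declared_constants = h.constants
    declared_types = h.types

    def check_symbol(sym: str, where: str):
        if sym.startswith("<"):
            if sym not in declared_types:
                findings.append(ValidationFinding("undeclared-symbol", f"{where}: type {sym}"))
        elif sym not in declared_constants:
            findings.append(ValidationFinding("undeclared-symbol", f"{where}: constant {sym}"))

    for wr in kb.word_rules:
        check_symbol(wr.output_constant, f"word rule for {wr.phrases[0]!r}")
        if wr.output_type:
            check_symbol(wr.output_type, f"word rule for {wr.phrases[0]!r}")
    referenced: set[str] = set()
    for rule in kb.grammar_rules + kb.abstract_rules:
        for e in rule.pattern:
            check_symbol(e, f"rule {rule.name}")
            referenced.add(e)
        if rule.result_constant:
            check_symbol(rule.result_constant, f"rule {rule.name}")
    for tm in kb.template_mappings:
        for c in (tm.affirmed_constant, tm.negated_constant):
            if c:
                check_symbol(c, f"template {tm.label!r}")
    target_constants = set()
    for tc in kb.target_concepts:
        check_symbol(tc.constant, f"target {tc.class_label!r}")
        target_constants.add(tc.constant)
    for rule in kb.grammar_rules:
        if (
            rule.result_constant not in target_constants
            and rule.result_constant not in referenced
            and not rule.interpretation
        ):
            findings.append(
                ValidationFinding(
                    "unreachable-rule",
                    f"rule {rule.name}: result {rule.result_constant} is never consumed",
                )
            )
    groups: dict[str, int] = {}
    for tc in kb.target_concepts:
        groups[tc.variable_group] = groups.get(tc.variable_group, 0) + 1
    if kb.target_concepts and sorted(groups.values()) != [2, 2, 3]:
        findings.append(
            ValidationFinding(
                "bad-target-partition",
                f"target concepts split {groups}, expected 3 housing / 2 living_alone / 2 social_support",
            )
        )
    return ValidationReport(findings)


def serialize_kb(kb: KnowledgeBase) -> dict:
    """Render every KB component back to its file dialect (a dict of
    filename -> text).  ``load`` of the result equals the original KB."""
    lines_h = []
    emitted: set[str] = set()

    def emit_type(t: str):
        if t in emitted:
            return
        for p in sorted(kb.hierarchy.parents[t]):
            emit_type(p)
        parents = " ".join(sorted(kb.hierarchy.parents[t]))
        lines_h.append(f"(deftype {t}{(' ' + parents) if parents else ''})")
        emitted.add(t)

    for t in sorted(kb.hierarchy.types):
        emit_type(t)
    by_type: dict[str, list] = {}
    for c, ts in sorted(kb.hierarchy.constant_types.items()):
        for t in sorted(ts):
            by_type.setdefault(t, []).append(c)
    for t in sorted(by_type):
        lines_h.append(f"(defconstants {t} {' '.join(by_type[t])})")

    lines_w = []
    for wr in kb.word_rules:
        t = f" {wr.output_type}" if wr.output_type else ""
        phrases = " ".join('"%s"' % p for p in wr.phrases)
        lines_w.append(f"(defwords {wr.output_constant}{t} {phrases})")

    def rule_text(rule: GrammarRule) -> str:
        head = "defabstract" if rule.is_abstract else "defrule"
        parts = [f"({head} {rule.name}", f"  (pattern {' '.join(rule.pattern)})"]
        if rule.tests:
            parts.append(f"  (tests {' '.join(to_sexpr(t) for t in rule.tests)})")
        if not rule.is_abstract:
            rt = f" {rule.result_type}" if rule.result_type else ""
            parts.append(f"  (result {rule.result_constant}{rt})")
        if rule.interpretation:
            parts.append(f"  (interp {' '.join(to_sexpr(p) for p in rule.interpretation)})")
        parts.append(f"  (weight {rule.weight})")
        parts.append(f"  (ordered {'true' if rule.ordered else 'false'})")
        parts.append(f"  (window {rule.window}))")
        return "\n".join(parts)

    lines_g = [rule_text(r) for r in kb.grammar_rules + kb.abstract_rules]
    lines_i = [
        f"(definfer {r.name} (if {to_sexpr(r.antecedent)}) (then {to_sexpr(r.consequent)}))"
        for r in kb.inference_rules
    ]
    lines_t = [
        "(deftemplate \"%s\" %s %s)"
        % (tm.label, tm.affirmed_constant or "nil", tm.negated_constant or "nil")
        for tm in kb.template_mappings
    ] + [
        f'(deftarget {tc.constant} {tc.variable_group} "{tc.class_label}")'
        for tc in kb.target_concepts
    ]
    negation = ["PRE " + " ".join(kb.negation_pre_triggers)] if False else None
    neg_lines = [f"PRE\t{t}" for t in kb.negation_pre_triggers] + [
        f"POST\t{t}" for t in kb.negation_post_triggers
    ]
    return {
        "hierarchy.tsl": "\n".join(lines_h) + "\n",
        "words.tsl": "\n".join(lines_w) + "\n",
        "grammar.tsl": "\n\n".join(lines_g) + "\n",
        "inference.tsl": "\n".join(lines_i) + "\n",
        "templates.tsl": "\n".join(lines_t) + "\n",
        "negation.txt": "\n".join(neg_lines) + "\n",
        "headers.txt": "\n".join(kb.header_lexicon) + "\n",
    }
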