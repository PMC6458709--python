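"""Bottom-up chart parsing with unordered pattern matching.

The parser is a CYK-flavoured bottom-up closure specialized for sparse
semantic grammars over mostly-unknown text: starting from word-level
annotations, each grammar rule may fire on *any* combination of existing
annotations with pairwise-disjoint token sets, one per pattern element —
in any order unless the rule is marked ordered, and with intervening
unmatched words allowed as long as the whole match stays inside the rule's
token window.  Validation tests (``notneg``, ``neg``, ``precedes``) are
evaluated with positional variables bound to the matched annotations.

Every firing yields a new annotation whose children are the matched
annotations in pattern order; closure is bounded by forbidding duplicate
(rule, child-set) firings and by a per-sentence firing budget, so parsing
terminates even on pathological rule sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import tsl
from .grammar import GrammarRule, KnowledgeBase, WordRule, evaluate_tests, match_element
from .textproc import SentenceSpan, Token

__all__ = [
    "Annotation",
    "ParseForest",
    "ParserConfig",
    "build_grammar_hosts",
    "apply_word_level",
    "detect_negation",
    "chart_parse",
    "score_tree",
    "select_interpretations",
    "apply_inference_rules",
]

_ids = itertools.count()


@dataclass
class ParserConfig:
    """Tunables for parsing, scoring and inference."""

    window: int = 10  # fallback token window for rules that set none
    budget: int = 5000  # max rule firings per sentence
    negation_scope: int = 5  # tokens a trigger reaches
    leaf_score: float = 1.0
    target_bonus: float = 0.2  # score bonus per task-relevant constant in a tree
    inference_depth: int = 32
    cross_sentence: bool = False


@dataclass
class Annotation:
    """A text span with a semantic summary and a TSL interpretation."""

    start: int
    end: int
    token_indices: frozenset
    summary_constant: str
    semantic_type: Optional[str] = None
    interpretation: tuple = ()
    negated: bool = False
    children: tuple = ()
    rule_name: str = ""
    score: float = 0.0
    weight: float = 1.0
    inferred: bool = False
    uid: int = field(default_factory=lambda: next(_ids))

    @property
    def min_token(self) -> int:
        return min(self.token_indices)

    @property
    def max_token(self) -> int:
        return max(self.token_indices)

    def check_structure(self) -> None:
        """Child token sets must be disjoint subsets; spans must nest."""
        seen: set[int] = set()
        for c in self.children:
            if c.token_indices & seen:
                raise ValueError(f"annotation {self.rule_name}: overlapping children")
            if not c.token_indices <= self.token_indices:
                raise ValueError(f"annotation {self.rule_name}: child tokens escape parent")
            if not (self.start <= c.start and c.end <= self.end):
                raise ValueError(f"annotation {self.rule_name}: child span escapes parent")
            seen |= c.token_indices
            c.check_structure()


@dataclass
class ParseForest:
    annotations: list  # every annotation produced (leaves + composites)
    truncated: bool = False  # firing budget was exhausted

    @property
    def roots(self) -> list:
        covered = {c.uid for a in self.annotations for c in a.children}
        return [a for a in self.annotations if a.uid not in covered]


def build_grammar_hosts() -> tsl.HostRegistry:
    """Host relations available to grammar validation tests."""
    hosts = tsl.HostRegistry()
    hosts.bind("notneg", 1, lambda a: not a.negated)
    hosts.bind("neg", 1, lambda a: a.negated)
    hosts.bind("precedes", 2, lambda a, b: a.min_token < b.min_token)
    return hosts


# ---------------------------------------------------------------------------
# Word level
# ---------------------------------------------------------------------------


def apply_word_level(
    sentence: SentenceSpan,
    tokens: Sequence[Token],
    word_rules: Sequence[WordRule],
) -> list[Annotation]:
    """Longest-match, left-to-right phrase matching over a sentence.

    Matching is case-insensitive on normalized tokens; a phrase must cover
    consecutive content (non-newline) tokens.
    """
    lo, hi = sentence.token_range
    content = [(i, tokens[i]) for i in range(lo, hi) if tokens[i].kind != "newline"]
    # index: first word of each phrase -> (phrase tokens, rule)
    index: dict[str, list] = {}
    for rule in word_rules:
        for phrase in rule.phrases:
            words = tuple(t.norm for t in _phrase_tokens(phrase))
            if words:
                index.setdefault(words[0], []).append((words, rule))
    for cands in index.values():
        cands.sort(key=lambda wr: -len(wr[0]))  # longest phrase first

    leaves: list[Annotation] = []
    i = 0
    while i < len(content):
        _, tok = content[i]
        best = None
        for words, rule in index.get(tok.norm, ()):
            if i + len(words) <= len(content) and all(
                content[i + k][1].norm == words[k] for k in range(len(words))
            ):
                best = (words, rule)
                break  # candidates sorted longest-first
        if best is None:
            i += 1
            continue
        words, rule = best
        span_toks = content[i : i + len(words)]
        leaves.append(
            Annotation(
                start=span_toks[0][1].start,
                end=span_toks[-1][1].end,
                token_indices=frozenset(idx for idx, _ in span_toks),
                summary_constant=rule.output_constant,
                semantic_type=rule.output_type,
                rule_name=f"word:{rule.output_constant}",
                weight=rule.weight,
            )
        )
        i += len(words)
    return leaves


def _phrase_tokens(phrase: str):
    from .textproc import tokenize

    return [t for t in tokenize(phrase) if t.kind in ("word", "number")]


# ---------------------------------------------------------------------------
# Negation
# ---------------------------------------------------------------------------


def detect_negation(
    sentence: SentenceSpan,
    tokens: Sequence[Token],
    annotation: Annotation,
    pre_triggers: Sequence[str],
    post_triggers: Sequence[str] = (),
    scope: int = 5,
) -> bool:
    """Trigger-and-scope negation in the NegEx style.

    A pre-trigger ("no", "not", "denies", ...) negates an annotation whose
    first token starts within *scope* content tokens after the trigger; a
    post-trigger negates one ending within *scope* tokens before it.
    Triggers inside the annotation itself do not count.
    """
    lo, hi = sentence.token_range
    content = [(i, tokens[i]) for i in range(lo, hi) if tokens[i].kind != "newline"]
    pos_of = {idx: p for p, (idx, _) in enumerate(content)}
    ann_positions = sorted(pos_of[i] for i in annotation.token_indices if i in pos_of)
    if not ann_positions:
        return False
    first, last = ann_positions[0], ann_positions[-1]

    def occurrences(trigger: str):
        words = tuple(t.norm for t in _phrase_tokens(trigger))
        for p in range(len(content) - len(words) + 1):
            if all(content[p + k][1].norm == words[k] for k in range(len(words))):
                if any(content[p + k][0] in annotation.token_indices for k in range(len(words))):
                    continue
                yield p, p + len(words) - 1

    for trig in pre_triggers:
        for _, t_end in occurrences(trig):
            if t_end < first <= t_end + scope:
                return True
    for trig in post_triggers:
        for t_start, _ in occurrences(trig):
            if t_start > last >= t_start - scope:
                return True
    return False


# ---------------------------------------------------------------------------
# Chart closure
# ---------------------------------------------------------------------------


def chart_parse(
    leaves: Sequence[Annotation],
    grammar_rules: Sequence[GrammarRule],
    hierarchy,
    hosts: Optional[tsl.HostRegistry] = None,
    config: Optional[ParserConfig] = None,
) -> ParseForest:
    """Bottom-up closure of the grammar over word-level annotations."""
    hosts = hosts or build_grammar_hosts()
    config = config or ParserConfig()
    annotations: list[Annotation] = list(leaves)
    fired: set[tuple] = set()
    firings = 0
    truncated = False

    changed = True
    while changed and not truncated:
        changed = False
        for rule in grammar_rules:
            window = rule.window or config.window
            for combo in _matches(rule, annotations, hierarchy):
                key = (rule.name, frozenset(a.uid for a in combo))
                if key in fired:
                    continue
                toks = frozenset().union(*(a.token_indices for a in combo))
                if max(toks) - min(toks) + 1 > window:
                    continue
                if rule.ordered:
                    starts = [a.min_token for a in combo]
                    if starts != sorted(starts) or len(set(starts)) != len(starts):
                        continue
                if not evaluate_tests(rule, combo, hosts):
                    fired.add(key)  # tests are deterministic; don't retry
                    continue
                fired.add(key)
                firings += 1
                interp = tuple(_instantiate(p, combo) for p in rule.interpretation)
                ordered_children = tuple(combo)
                annotations.append(
                    Annotation(
                        start=min(a.start for a in combo),
                        end=max(a.end for a in combo),
                        token_indices=toks,
                        summary_constant=rule.result_constant or ":ABSTRACT_MATCH:",
                        semantic_type=rule.result_type,
                        interpretation=interp,
                        children=ordered_children,
                        rule_name=rule.name,
                        weight=rule.weight,
                    )
                )
                changed = True
                if firings >= config.budget:
                    truncated = True
                    break
            if truncated:
                break
    return ParseForest(annotations, truncated)


def _matches(rule: GrammarRule, annotations: Sequence[Annotation], hierarchy):
    """Enumerate tuples of annotations matching the pattern elements, with
    pairwise-disjoint token sets.  Deterministic order (by uid)."""
    candidates = []
    for element in rule.pattern:
        fits = [a for a in annotations if match_element(element, a, hierarchy)]
        if not fits:
            return
        candidates.append(fits)

    def rec(pos: int, chosen: list, used: frozenset):
        if pos == len(candidates):
            yield tuple(chosen)
            return
        for a in candidates[pos]:
            if a.token_indices & used:
                continue
            yield from rec(pos + 1, chosen + [a], used | a.token_indices)

    yield from rec(0, [], frozenset())


def _instantiate(pred: tsl.Expression, combo) -> tsl.Expression:
    """Replace positional variables in an interpretation predicate with the
    matched annotations' summary constants."""
    mapping = {
        v: tsl.ObjectConstant(combo[v.position - 1].summary_constant)
        for v in tsl.variables_of(pred)
        if v.is_positional
    }
    return tsl.substitute(pred, mapping)


# ---------------------------------------------------------------------------
# Scoring and selection
# ---------------------------------------------------------------------------


def score_tree(
    root: Annotation,
    target_constants: frozenset,
    config: Optional[ParserConfig] = None,
) -> float:
    """Tree likelihood proxy: product of rule weights along the tree times
    a prevalence bonus, ``(1 + bonus)`` per task-relevant constant found."""
    config = config or ParserConfig()

    def weight_product(a: Annotation) -> float:
        w = a.weight if a.children or a.rule_name.startswith("word:") else a.weight
        for c in a.children:
            w *= weight_product(c)
        return w

    def target_count(a: Annotation) -> int:
        n = 1 if a.summary_constant in target_constants else 0
        return n + sum(target_count(c) for c in a.children)

    base = config.leaf_score * weight_product(root)
    return base * (1.0 + config.target_bonus) ** target_count(root)


def select_interpretations(
    forest: ParseForest,
    kb: KnowledgeBase,
    config: Optional[ParserConfig] = None,
) -> list[Annotation]:
    """Greedy selection of the most likely task-relevant annotations.

    Candidates (annotations whose summary constant is a target concept) are
    taken in descending score order; one is kept unless its tokens overlap
    an already-kept annotation from the same variable group.  Ties break
    toward larger token coverage, then earlier span, then rule name.
    """
    config = config or ParserConfig()
    targets = {t.constant: t for t in kb.target_concepts}
    candidates = [a for a in forest.annotations if a.summary_constant in targets]
    for a in candidates:
        a.score = score_tree(a, frozenset(targets), config)
    candidates.sort(
        key=lambda a: (-a.score, -len(a.token_indices), a.start, a.end, a.rule_name)
    )
    kept: list[Annotation] = []
    for a in candidates:
        group = targets[a.summary_constant].variable_group
        clash = any(
            targets[k.summary_constant].variable_group == group
            and (k.token_indices & a.token_indices)
            for k in kept
        )
        if not clash:
            kept.append(a)
    kept.sort(key=lambda a: (a.start, a.end))
    return kept


# ---------------------------------------------------------------------------
# Sentence-level inference
# ---------------------------------------------------------------------------


def sentence_facts(annotations: Sequence[Annotation], hierarchy) -> set:
    """Fact set describing one parsed sentence.

    Structural facts: ``(subject C)`` for the earliest person-typed leaf,
    ``(affirmed C)`` / ``(negated C)`` for every annotation's summary
    constant, plus every ground interpretation predicate.
    """
    facts: set = set()
    person_leaves = [
        a
        for a in annotations
        if not a.children
        and a.summary_constant in hierarchy.constants
        and hierarchy.subsumes("<PERSON>", a.summary_constant)
    ]
    if person_leaves:
        subject = min(person_leaves, key=lambda a: (a.start, a.end))
        facts.add(tsl.Compound("subject", (tsl.ObjectConstant(subject.summary_constant),)))
    for a in annotations:
        rel = "negated" if a.negated else "affirmed"
        facts.add(tsl.Compound(rel, (tsl.ObjectConstant(a.summary_constant),)))
        for p in a.interpretation:
            if tsl.is_ground(p) and isinstance(p, tsl.Compound):
                facts.add(p)
    return facts


def build_inference_hosts(hierarchy) -> tsl.HostRegistry:
    """Host relations available to inference rules (type subsumption)."""
    hosts = tsl.HostRegistry()

    def isa(x, t):
        name_x = x.name if hasattr(x, "name") else str(x)
        name_t = t.name if hasattr(t, "name") else str(t)
        try:
            return hierarchy.subsumes(name_t, name_x)
        except tsl.HierarchyError:
            return False

    hosts.bind("isa", 2, isa)
    return hosts


def apply_inference_rules(
    selected: Sequence[Annotation],
    all_annotations: Sequence[Annotation],
    inference_rules,
    hierarchy,
    kb: KnowledgeBase,
    hosts: Optional[tsl.HostRegistry] = None,
) -> list[Annotation]:
    """Forward-chain the sentence fact set and attach newly derived
    task-relevant conclusions as inferred annotations.

    A derived ``(concept :C:)`` with a target constant ``:C:`` becomes a new
    annotation spanning the sentence's evidence annotations — unless the
    sentence already carries that class (idempotence).
    """
    hosts = hosts or build_inference_hosts(hierarchy)
    facts = sentence_facts(all_annotations, hierarchy)
    closure = tsl.forward_chain(facts, inference_rules, hosts)
    present_classes = {kb.class_of(a.summary_constant) for a in selected}
    out = list(selected)
    derived = []
    for fact in closure:
        if isinstance(fact, tsl.Compound) and fact.relation == "concept" and len(fact.args) == 1:
            arg = fact.args[0]
            if isinstance(arg, tsl.ObjectConstant):
                derived.append(arg.name)
    for constant in sorted(set(derived)):
        cls = kb.class_of(constant)
        if cls is None or cls in present_classes:
            continue
        evidence = [a for a in all_annotations if not a.inferred]
        if not evidence:
            continue
        out.append(
            Annotation(
                start=min(a.start for a in evidence),
                end=max(a.end for a in evidence),
                token_indices=frozenset().union(*(a.token_indices for a in evidence)),
                summary_constant=constant,
                interpretation=(tsl.Compound("concept", (tsl.ObjectConstant(constant),)),),
                rule_name="inference",
                inferred=True,
                score=1.0,
            )
        )
        present_classes.add(cls)
    out.sort(key=lambda a: (a.start, a.end))
    return out
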