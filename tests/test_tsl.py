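"""The TSL logic layer: reader, hierarchy, unification, truth, chaining."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from moonstone import tsl
from moonstone.tsl import (
    And,
    Compound,
    HierarchyError,
    HostRegistry,
    InferenceRule,
    Not,
    ObjectConstant,
    Symbol,
    TSLSyntaxError,
    TypeName,
    Variable,
    backward_chain,
    evaluate_truth,
    forward_chain,
    load_type_hierarchy,
    read_expression,
    to_sexpr,
    unify,
)


def C(name, *args):
    return Compound(name, tuple(args))


PATIENT = ObjectConstant(":PATIENT:")
X = Variable("?x")


class TestReader:
    def test_support_expression_structure(self):
        e = read_expression("(and (has-support ?patient) (not (lives-alone ?patient)))")
        assert isinstance(e, And) and len(e.args) == 2
        assert e.args[0] == C("has-support", Variable("?patient"))
        assert e.args[1] == Not(C("lives-alone", Variable("?patient")))

    def test_positional_variable(self):
        e = read_expression("(notneg ?1)")
        assert e == C("notneg", Variable("?1"))
        assert e.args[0].is_positional and e.args[0].position == 1

    @pytest.mark.parametrize("bad", ["(foo", "()", "(not a b)", "(foo) bar", ""])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(TSLSyntaxError) as exc:
            read_expression(bad)
        assert exc.value.position >= 0

    def test_comments_stripped(self):
        assert read_expression("; note\n(r :A:) ; tail") == C("r", ObjectConstant(":A:"))


# expression generator for the print/read round trip
_atoms = st.one_of(
    st.sampled_from([PATIENT, ObjectConstant(":SPOUSE:"), TypeName("<PERSON>"), X, Variable("?1"), Symbol("rel")]),
)


def _exprs(depth=2):
    if depth == 0:
        return _atoms
    sub = _exprs(depth - 1)
    return st.one_of(
        _atoms,
        st.builds(lambda a: C("r", *a), st.lists(sub, min_size=1, max_size=3)),
        st.builds(lambda a: And(tuple(a)), st.lists(sub, min_size=1, max_size=3)),
        st.builds(Not, sub),
    )


class TestPrintReadRoundTrip:
    @given(_exprs())
    def test_identity(self, expr):
        assert read_expression(to_sexpr(expr)) == expr


HIERARCHY_TEXT = """
(deftype <ENTITY>)
(deftype <PERSON> <ENTITY>)
(deftype <FRIEND_FAMILY> <PERSON>)
(deftype <SOCIAL_SUPPORT> <ENTITY>)
(defconstants <PERSON> :PATIENT:)
(defconstants <FRIEND_FAMILY> :SPOUSE:)
(defconstants <SOCIAL_SUPPORT> :HAVE_SUPPORT:)
"""


class TestHierarchy:
    def test_membership_and_subsumption(self):
        h = load_type_hierarchy(HIERARCHY_TEXT)
        assert h.subsumes("<PERSON>", ":SPOUSE:")
        assert h.subsumes("<PERSON>", "<PERSON>")  # reflexive
        assert not h.subsumes("<SOCIAL_SUPPORT>", "<PERSON>")
        assert not h.subsumes("<FRIEND_FAMILY>", ":PATIENT:")

    def test_empty_definition(self):
        h = load_type_hierarchy("")
        assert h.types == frozenset() and h.constants == frozenset()

    def test_self_parent_cycle_rejected(self):
        with pytest.raises(HierarchyError):
            load_type_hierarchy("(deftype <A> <A>)")

    def test_constant_under_unknown_type_rejected(self):
        with pytest.raises(HierarchyError):
            load_type_hierarchy("(defconstants <NOPE> :X:)")

    def test_unknown_name_errors(self):
        h = load_type_hierarchy(HIERARCHY_TEXT)
        with pytest.raises(HierarchyError):
            h.subsumes("<PERSON>", ":UNKNOWN:")

    def test_subsumption_partial_order_on_types(self):
        h = load_type_hierarchy(HIERARCHY_TEXT)
        types = sorted(h.types)
        for a in types:
            assert h.subsumes(a, a)
        for a, b, c in itertools.product(types, repeat=3):
            if h.subsumes(a, b) and h.subsumes(b, c):
                assert h.subsumes(a, c)
            if h.subsumes(a, b) and h.subsumes(b, a):
                assert a == b


class TestUnify:
    def test_single_substitution(self):
        b = unify(C("has-support", Variable("?patient")), C("has-support", PATIENT))
        assert b == {Variable("?patient"): PATIENT}

    def test_ground_identity(self):
        assert unify(C("r", PATIENT), C("r", PATIENT)) == {}

    def test_clash_fails(self):
        assert unify(C("r", X, X), C("r", ObjectConstant(":A:"), ObjectConstant(":B:"))) is None

    def test_occurs_check(self):
        assert unify(X, C("r", X)) is None

    def test_mgu_applies_to_both_sides(self):
        a, b = C("r", X, ObjectConstant(":B:")), C("r", ObjectConstant(":A:"), Variable("?y"))
        sub = unify(a, b)
        assert tsl.substitute(a, sub) == tsl.substitute(b, sub)


class TestTruth:
    def test_conjunction_with_negation(self):
        facts = {C("has-support", PATIENT)}
        e = read_expression("(and (has-support :PATIENT:) (not (lives-alone :PATIENT:)))")
        assert evaluate_truth(e, facts)

    def test_negated_fact_false(self):
        assert not evaluate_truth(Not(C("r", PATIENT)), {C("r", PATIENT)})

    def test_empty_facts_atomic_false(self):
        assert not evaluate_truth(C("r", PATIENT), set())

    def test_non_ground_raises(self):
        with pytest.raises(tsl.TSLError):
            evaluate_truth(C("r", X), set())


class TestHosts:
    def test_bind_and_evaluate(self):
        hosts = HostRegistry().bind("notneg", 1, lambda a: a != Symbol("negated"))
        assert evaluate_truth(C("notneg", Symbol("a")), set(), hosts)

    def test_duplicate_bind_errors(self):
        hosts = HostRegistry().bind("f", 1, bool)
        with pytest.raises(tsl.TSLError):
            hosts.bind("f", 1, bool)

    def test_unbound_relation_defaults_to_facts(self):
        assert not evaluate_truth(C("mystery", PATIENT), set())


RULE_AB = InferenceRule("ab", C("A", X), C("B", X))
RULE_BC = InferenceRule("bc", C("B", X), C("CC", X))


class TestForwardChain:
    def test_one_step(self):
        closure = forward_chain({C("A", ObjectConstant(":P:"))}, [RULE_AB])
        assert C("B", ObjectConstant(":P:")) in closure

    def test_no_rules_is_identity(self):
        facts = frozenset({C("A", PATIENT)})
        assert forward_chain(facts, []) == facts

    def test_two_step_chain(self):
        closure = forward_chain({C("A", ObjectConstant(":P:"))}, [RULE_AB, RULE_BC])
        assert C("CC", ObjectConstant(":P:")) in closure

    def test_monotone_and_idempotent(self):
        small = {C("A", ObjectConstant(":P:"))}
        big = small | {C("A", ObjectConstant(":Q:"))}
        rules = [RULE_AB, RULE_BC]
        assert forward_chain(small, rules) <= forward_chain(big, rules)
        once = forward_chain(small, rules)
        assert forward_chain(once, rules) == once

    def test_consequent_variable_must_occur_in_antecedent(self):
        with pytest.raises(tsl.TSLError):
            InferenceRule("bad", C("A", X), C("B", Variable("?free")))


class TestBackwardChain:
    def test_single_rule_binding(self):
        res = backward_chain(C("B", X), {C("A", ObjectConstant(":P:"))}, [RULE_AB])
        assert res.bindings == [{X: ObjectConstant(":P:")}]
        assert not res.truncated

    def test_unprovable_goal(self):
        assert backward_chain(C("Z", X), {C("A", PATIENT)}, [RULE_AB]).bindings == []

    def test_recursive_rules_terminate(self):
        # transitive closure over a small cycle must terminate and be complete
        e = lambda a, b: C("edge", ObjectConstant(a), ObjectConstant(b))
        facts = {e(":A:", ":B:"), e(":B:", ":C:"), e(":C:", ":A:")}
        y = Variable("?y")
        z = Variable("?z")
        rules = [
            InferenceRule("base", C("path", X, y), C("path", X, y)),
            InferenceRule("step", And((C("edge", X, y), C("path", y, z))), C("path", X, z)),
            InferenceRule("edge-path", C("edge", X, y), C("path", X, y)),
        ]
        res = backward_chain(C("path", ObjectConstant(":A:"), z), facts, rules)
        found = {b[z].name for b in res.bindings}
        assert found == {":A:", ":B:", ":C:"}


def _random_kb(rng):
    """Function-free KB with <=5 constants and <=5 rules."""
    consts = [ObjectConstant(f":C{i}:") for i in range(rng.randint(1, 5))]
    rels = [f"r{i}" for i in range(rng.randint(1, 3))]
    arities = {r: rng.randint(1, 2) for r in rels}
    facts = set()
    for _ in range(rng.randint(1, 6)):
        r = rng.choice(rels)
        facts.add(C(r, *(rng.choice(consts) for _ in range(arities[r]))))
    rules = []
    for i in range(rng.randint(1, 5)):
        vs = [Variable(f"?x{j}") for j in range(rng.randint(1, 2))]
        ante = []
        for _ in range(rng.randint(1, 2)):
            r = rng.choice(rels)
            ante.append(C(r, *(rng.choice(vs + consts[:1]) for _ in range(arities[r]))))
        avars = sorted(set().union(*[tsl.variables_of(a) for a in ante]), key=lambda v: v.name)
        r = rng.choice(rels)
        cargs = tuple(
            rng.choice(avars) if (avars and rng.random() < 0.7) else rng.choice(consts)
            for _ in range(arities[r])
        )
        rules.append(InferenceRule(f"rule{i}", And(tuple(ante)) if len(ante) > 1 else ante[0], C(r, *cargs)))
    return consts, arities, facts, rules


def _enumeration_closure(consts, arities, facts, rules):
    """Independent oracle: try every ground substitution naively."""
    closure = set(facts)
    changed = True
    while changed:
        changed = False
        for rule in rules:
            vs = sorted(tsl.variables_of(rule.antecedent), key=lambda v: v.name)
            for combo in itertools.product(consts, repeat=len(vs)):
                b = dict(zip(vs, combo))
                ante = tsl.substitute(rule.antecedent, b)
                parts = list(ante.args) if isinstance(ante, And) else [ante]
                if all(p in closure for p in parts):
                    c = tsl.substitute(rule.consequent, b)
                    if c not in closure:
                        closure.add(c)
                        changed = True
    return closure


def check_chaining_agreement(n_kbs: int, seed: int) -> int:
    """Forward closure == enumeration oracle, and backward provability ==
    closure membership, over *n_kbs* random KBs.  Returns disagreements."""
    rng = random.Random(seed)
    disagreements = 0
    for _ in range(n_kbs):
        consts, arities, facts, rules = _random_kb(rng)
        oracle = _enumeration_closure(consts, arities, facts, rules)
        if forward_chain(facts, rules) != frozenset(oracle):
            disagreements += 1
            continue
        for rel, ar in arities.items():
            for args in itertools.product(consts, repeat=ar):
                goal = C(rel, *args)
                proved = bool(backward_chain(goal, facts, rules).bindings)
                if proved != (goal in oracle):
                    disagreements += 1
    return disagreements


class TestChainingAgreement:
    def test_forward_backward_match_enumeration_oracle(self):
        assert check_chaining_agreement(40, seed=20260920) == 0
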