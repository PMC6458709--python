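"""Typed Semantic Language (TSL): a function-free first-order logic.

TSL is the meaning-representation layer of the pipeline.  Expressions are
S-expressions built from three atom kinds — object constants written with
colon delimiters (``:SPOUSE:``), semantic type names written with angle
brackets (``<PERSON>``), and variables written with a ``?`` prefix
(``?patient``, or positional ``?1`` inside grammar validation tests) —
combined by relation application ``(relation arg ...)`` and the logical
operators ``and``, ``or`` and ``not``.

A type hierarchy declares semantic types, their parent types, and which
object constants belong to which types; subsumption over that hierarchy is
the matching relation used throughout the semantic grammar.

Because the language is function-free and the constant vocabulary is finite,
forward chaining reaches a least fixpoint and terminates; backward chaining
is additionally depth-bounded so that recursive rule sets cannot loop.

Host relations let the surrounding environment supply the truth value of a
relation (e.g. the ``notneg`` test consulted by grammar rules): a registered
side-effect-free function is called on ground arguments instead of looking
the atom up in the fact set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "TSLError",
    "TSLSyntaxError",
    "HierarchyError",
    "ObjectConstant",
    "TypeName",
    "Variable",
    "Symbol",
    "Compound",
    "And",
    "Or",
    "Not",
    "Expression",
    "read_expression",
    "read_all",
    "to_sexpr",
    "variables_of",
    "constants_of",
    "is_ground",
    "substitute",
    "unify",
    "TypeHierarchy",
    "load_type_hierarchy",
    "InferenceRule",
    "HostRegistry",
    "bind_host_relation",
    "evaluate_truth",
    "forward_chain",
    "backward_chain",
]


class TSLError(Exception):
    """Base error for the TSL layer."""


class TSLSyntaxError(TSLError):
    """Malformed S-expression text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class HierarchyError(TSLError):
    """Ill-formed type hierarchy (cycles, undeclared types)."""


# ---------------------------------------------------------------------------
# Expression algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectConstant:
    """Colon-delimited object constant, e.g. ``:SPOUSE:``."""

    name: str  # includes the delimiters


@dataclass(frozen=True)
class TypeName:
    """Angle-bracket semantic type, e.g. ``<PERSON>``."""

    name: str  # includes the delimiters


@dataclass(frozen=True)
class Variable:
    """``?``-prefixed variable; ``?1`` .. ``?9`` are positional."""

    name: str  # includes the "?"

    @property
    def is_positional(self) -> bool:
        return self.name[1:].isdigit()

    @property
    def position(self) -> int:
        return int(self.name[1:])


@dataclass(frozen=True)
class Symbol:
    """Bare symbol atom (relation names used as arguments, plain words)."""

    name: str


@dataclass(frozen=True)
class Compound:
    """Relation application ``(relation arg1 arg2 ...)``."""

    relation: str
    args: tuple["Expression", ...]

    def __post_init__(self):
        if not self.args:
            raise TSLError(f"compound ({self.relation}) needs at least one argument")


@dataclass(frozen=True)
class And:
    args: tuple["Expression", ...]


@dataclass(frozen=True)
class Or:
    args: tuple["Expression", ...]


@dataclass(frozen=True)
class Not:
    arg: "Expression"


Expression = Union[ObjectConstant, TypeName, Variable, Symbol, Compound, And, Or, Not]
Atom = Union[ObjectConstant, TypeName, Variable, Symbol]


# ---------------------------------------------------------------------------
# Reader / printer
# ---------------------------------------------------------------------------


def _strip_comments(text: str) -> str:
    # ";" starts a comment running to end of line; preserve char positions
    out = []
    in_comment = False
    for ch in text:
        if ch == "\n":
            in_comment = False
            out.append(ch)
        elif in_comment:
            out.append(" ")
        elif ch == ";":
            in_comment = True
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def _tokenize_sexpr(text: str) -> Iterator[tuple[str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            yield ch, i
            i += 1
        elif ch == '"':
            j = i + 1
            while j < n and text[j] != '"':
                j += 1
            if j >= n:
                raise TSLSyntaxError("unterminated string", i)
            yield text[i : j + 1], i
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            yield text[i:j], i
            i = j


def _atom(token: str) -> Atom:
    if len(token) >= 3 and token.startswith(":") and token.endswith(":"):
        return ObjectConstant(token)
    if len(token) >= 3 and token.startswith("<") and token.endswith(">"):
        return TypeName(token)
    if token.startswith("?") and len(token) > 1:
        return Variable(token)
    if token.startswith('"') and token.endswith('"'):
        return Symbol(token[1:-1])
    return Symbol(token)


def _read_form(tokens: list[tuple[str, int]], pos: int) -> tuple[Expression, int]:
    token, at = tokens[pos]
    if token == "(":
        items: list[Expression] = []
        head: Optional[str] = None
        i = pos + 1
        first = True
        while True:
            if i >= len(tokens):
                raise TSLSyntaxError("unbalanced parentheses", at)
            t, t_at = tokens[i]
            if t == ")":
                i += 1
                break
            if first and t not in "()":
                head = t
                first = False
                i += 1
                continue
            first = False
            expr, i = _read_form(tokens, i)
            items.append(expr)
        if head is None:
            raise TSLSyntaxError("empty or headless compound", at)
        if head == "and":
            return And(tuple(items)), i
        if head == "or":
            return Or(tuple(items)), i
        if head == "not":
            if len(items) != 1:
                raise TSLSyntaxError("'not' takes exactly one argument", at)
            return Not(items[0]), i
        if not items:
            raise TSLSyntaxError(f"empty compound ({head})", at)
        return Compound(head, tuple(items)), i
    if token == ")":
        raise TSLSyntaxError("unexpected ')'", at)
    return _atom(token), pos + 1


def read_expression(text: str) -> Expression:
    """Parse one TSL expression from S-expression *text*.

    Raises :class:`TSLSyntaxError` (with character position) on unbalanced
    parentheses, empty compounds, or trailing garbage.
    """
    tokens = list(_tokenize_sexpr(_strip_comments(text)))
    if not tokens:
        raise TSLSyntaxError("empty input", 0)
    expr, end = _read_form(tokens, 0)
    if end != len(tokens):
        raise TSLSyntaxError("trailing content after expression", tokens[end][1])
    return expr


def read_all(text: str) -> list[Expression]:
    """Parse every top-level form in *text* (comments allowed)."""
    tokens = list(_tokenize_sexpr(_strip_comments(text)))
    forms: list[Expression] = []
    i = 0
    while i < len(tokens):
        expr, i = _read_form(tokens, i)
        forms.append(expr)
    return forms


def to_sexpr(expr: Expression) -> str:
    """Print *expr* so that ``read_expression(to_sexpr(e)) == e``."""
    if isinstance(expr, (ObjectConstant, TypeName, Variable)):
        return expr.name
    if isinstance(expr, Symbol):
        if expr.name == "" or any(c.isspace() or c in '();"' for c in expr.name):
            return '"%s"' % expr.name
        return expr.name
    if isinstance(expr, And):
        return "(and %s)" % " ".join(to_sexpr(a) for a in expr.args)
    if isinstance(expr, Or):
        return "(or %s)" % " ".join(to_sexpr(a) for a in expr.args)
    if isinstance(expr, Not):
        return "(not %s)" % to_sexpr(expr.arg)
    if isinstance(expr, Compound):
        return "(%s %s)" % (expr.relation, " ".join(to_sexpr(a) for a in expr.args))
    raise TypeError(f"not a TSL expression: {expr!r}")


def variables_of(expr: Expression) -> frozenset[Variable]:
    if isinstance(expr, Variable):
        return frozenset([expr])
    if isinstance(expr, (Compound, And, Or)):
        out: frozenset[Variable] = frozenset()
        for a in expr.args:
            out |= variables_of(a)
        return out
    if isinstance(expr, Not):
        return variables_of(expr.arg)
    return frozenset()


def constants_of(expr: Expression) -> frozenset[str]:
    if isinstance(expr, ObjectConstant):
        return frozenset([expr.name])
    if isinstance(expr, (Compound, And, Or)):
        out: frozenset[str] = frozenset()
        for a in expr.args:
            out |= constants_of(a)
        return out
    if isinstance(expr, Not):
        return constants_of(expr.arg)
    return frozenset()


def is_ground(expr: Expression) -> bool:
    return not variables_of(expr)


# ---------------------------------------------------------------------------
# Bindings and unification
# ---------------------------------------------------------------------------

Bindings = dict  # Variable -> Expression


def _walk(expr: Expression, bindings: Mapping) -> Expression:
    while isinstance(expr, Variable) and expr in bindings:
        expr = bindings[expr]
    return expr


def substitute(expr: Expression, bindings: Mapping) -> Expression:
    """Apply *bindings* throughout *expr* (resolving chains)."""
    expr = _walk(expr, bindings)
    if isinstance(expr, Compound):
        return Compound(expr.relation, tuple(substitute(a, bindings) for a in expr.args))
    if isinstance(expr, And):
        return And(tuple(substitute(a, bindings) for a in expr.args))
    if isinstance(expr, Or):
        return Or(tuple(substitute(a, bindings) for a in expr.args))
    if isinstance(expr, Not):
        return Not(substitute(expr.arg, bindings))
    return expr


def _occurs(var: Variable, expr: Expression, bindings: Mapping) -> bool:
    expr = _walk(expr, bindings)
    if expr == var:
        return True
    if isinstance(expr, (Compound, And, Or)):
        return any(_occurs(var, a, bindings) for a in expr.args)
    if isinstance(expr, Not):
        return _occurs(var, expr.arg, bindings)
    return False


def unify(a: Expression, b: Expression, bindings: Optional[Bindings] = None):
    """Most general unifier of *a* and *b* extending *bindings*.

    Returns a new bindings dict, or ``None`` on failure.  The occurs check
    is on: no variable is ever bound to an expression containing itself.
    """
    if bindings is None:
        bindings = {}
    a = _walk(a, bindings)
    b = _walk(b, bindings)
    if a == b:
        return dict(bindings)
    if isinstance(a, Variable):
        if _occurs(a, b, bindings):
            return None
        out = dict(bindings)
        out[a] = b
        return out
    if isinstance(b, Variable):
        return unify(b, a, bindings)
    if isinstance(a, Compound) and isinstance(b, Compound):
        if a.relation != b.relation or len(a.args) != len(b.args):
            return None
        for x, y in zip(a.args, b.args):
            bindings = unify(x, y, bindings)
            if bindings is None:
                return None
        return dict(bindings)
    for cls in (And, Or):
        if isinstance(a, cls) and isinstance(b, cls):
            if len(a.args) != len(b.args):
                return None
            for x, y in zip(a.args, b.args):
                bindings = unify(x, y, bindings)
                if bindings is None:
                    return None
            return dict(bindings)
    if isinstance(a, Not) and isinstance(b, Not):
        return unify(a.arg, b.arg, bindings)
    return None


# ---------------------------------------------------------------------------
# Type hierarchy
# ---------------------------------------------------------------------------


@dataclass
class TypeHierarchy:
    """Semantic types, parent edges, and constant membership declarations."""

    parents: dict = field(default_factory=dict)  # type name -> set of parent type names
    constant_types: dict = field(default_factory=dict)  # constant name -> set of type names

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def constants(self) -> frozenset[str]:
        return frozenset(self.constant_types)

    def declare_type(self, name: str, parent_names: Sequence[str] = ()) -> None:
        self.parents.setdefault(name, set())
        for p in parent_names:
            if p not in self.parents:
                raise HierarchyError(f"parent type {p} of {name} is not declared")
            self.parents[name].add(p)
        self._check_acyclic(name)

    def declare_constant(self, constant: str, type_names: Sequence[str]) -> None:
        for t in type_names:
            if t not in self.parents:
                raise HierarchyError(f"constant {constant} declared under unknown type {t}")
        self.constant_types.setdefault(constant, set()).update(type_names)

    def _check_acyclic(self, start: str) -> None:
        seen: set[str] = set()
        stack = [start]
        while stack:
            t = stack.pop()
            for p in self.parents.get(t, ()):
                if p == start:
                    raise HierarchyError(f"cycle in type hierarchy through {start}")
                if p not in seen:
                    seen.add(p)
                    stack.append(p)

    def ancestors(self, type_name: str) -> frozenset[str]:
        """All types reachable via parent edges, *including* type_name."""
        if type_name not in self.parents:
            raise HierarchyError(f"unknown type {type_name}")
        out = {type_name}
        stack = [type_name]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return frozenset(out)

    def subsumes(self, general: str, specific: str) -> bool:
        """True iff *general* (a type) covers *specific* (type or constant).

        A type subsumes itself, every descendant type, and every object
        constant declared under it or under a descendant.
        """
        if general not in self.parents:
            raise HierarchyError(f"unknown type {general}")
        if specific in self.parents:
            return general in self.ancestors(specific)
        if specific in self.constant_types:
            return any(general in self.ancestors(t) for t in self.constant_types[specific])
        raise HierarchyError(f"unknown name {specific}")


def load_type_hierarchy(text: str) -> TypeHierarchy:
    """Load a hierarchy from ``(deftype <T> <PARENT>...)`` and
    ``(defconstants <T> :C:...)`` forms."""
    h = TypeHierarchy()
    for form in read_all(text):
        if not isinstance(form, Compound):
            raise HierarchyError(f"unexpected form in hierarchy: {to_sexpr(form)}")
        if form.relation == "deftype":
            names = [a for a in form.args if isinstance(a, TypeName)]
            if len(names) != len(form.args) or not names:
                raise HierarchyError(f"bad deftype form: {to_sexpr(form)}")
            h.declare_type(names[0].name, [t.name for t in names[1:]])
        elif form.relation == "defconstants":
            if not isinstance(form.args[0], TypeName):
                raise HierarchyError(f"defconstants needs a type: {to_sexpr(form)}")
            t = form.args[0].name
            for c in form.args[1:]:
                if not isinstance(c, ObjectConstant):
                    raise HierarchyError(f"bad constant in defconstants: {to_sexpr(c)}")
                h.declare_constant(c.name, [t])
        else:
            raise HierarchyError(f"unknown hierarchy form ({form.relation} ...)")
    return h


# ---------------------------------------------------------------------------
# Host relations
# ---------------------------------------------------------------------------


@dataclass
class HostRegistry:
    """Relations evaluated by host-environment functions.

    Mirrors the original design of importing host-language methods as
    relation constants; here a host relation is any side-effect-free Python
    callable of the declared arity returning a truth value.
    """

    _bindings: dict = field(default_factory=dict)  # name -> (arity, fn)

    def bind(self, name: str, arity: int, fn: Callable[..., bool]) -> "HostRegistry":
        if name in self._bindings:
            raise TSLError(f"host relation {name!r} already bound")
        self._bindings[name] = (arity, fn)
        return self

    def is_bound(self, name: str) -> bool:
        return name in self._bindings

    def call(self, name: str, args: Sequence) -> bool:
        arity, fn = self._bindings[name]
        if len(args) != arity:
            raise TSLError(f"host relation {name!r} expects {arity} args, got {len(args)}")
        return bool(fn(*args))


def bind_host_relation(registry: HostRegistry, name: str, arity: int, fn) -> HostRegistry:
    """Functional spelling of :meth:`HostRegistry.bind`."""
    return registry.bind(name, arity, fn)


_EMPTY_HOSTS = HostRegistry()


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------


def evaluate_truth(
    expr: Expression,
    facts: Iterable[Expression],
    hosts: Optional[HostRegistry] = None,
    bindings: Optional[Mapping] = None,
) -> bool:
    """Truth of *expr* against a ground fact set, with host relations.

    A compound is true iff it is in *facts* or its relation is host-bound
    and the host call returns true; ``and``/``or``/``not`` have their usual
    semantics.  *expr* must be ground after applying *bindings*.
    """
    hosts = hosts or _EMPTY_HOSTS
    if bindings:
        expr = substitute(expr, bindings)
    if not is_ground(expr):
        raise TSLError(f"cannot evaluate non-ground expression {to_sexpr(expr)}")
    fact_set = facts if isinstance(facts, (set, frozenset)) else set(facts)
    return _truth(expr, fact_set, hosts)


def _truth(expr: Expression, facts: set, hosts: HostRegistry) -> bool:
    if isinstance(expr, And):
        return all(_truth(a, facts, hosts) for a in expr.args)
    if isinstance(expr, Or):
        return any(_truth(a, facts, hosts) for a in expr.args)
    if isinstance(expr, Not):
        return not _truth(expr.arg, facts, hosts)
    if isinstance(expr, Compound):
        if expr in facts:
            return True
        if hosts.is_bound(expr.relation):
            return hosts.call(expr.relation, expr.args)
        return False
    # bare atoms: true iff asserted as facts
    return expr in facts


# ---------------------------------------------------------------------------
# Inference rules and chaining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InferenceRule:
    """``antecedent => consequent``; every consequent variable must occur in
    the antecedent so that fired consequents are ground."""

    name: str
    antecedent: Expression
    consequent: Expression

    def __post_init__(self):
        missing = variables_of(self.consequent) - variables_of(self.antecedent)
        if missing:
            names = ", ".join(sorted(v.name for v in missing))
            raise TSLError(f"rule {self.name}: consequent variables {names} not in antecedent")


def _conjuncts(expr: Expression) -> list[Expression]:
    if isinstance(expr, And):
        out: list[Expression] = []
        for a in expr.args:
            out.extend(_conjuncts(a))
        return out
    return [expr]


def _match_conjuncts(
    conjuncts: Sequence[Expression],
    facts: set,
    hosts: HostRegistry,
    bindings: Bindings,
) -> Iterator[Bindings]:
    """Enumerate all bindings satisfying a conjunction.

    Fact-pattern conjuncts are matched against the fact set; host-bound and
    negated conjuncts are deferred until their variables are ground.
    """
    if not conjuncts:
        yield bindings
        return
    # pick the first conjunct that is decidable now: a fact pattern, or a
    # host/negative conjunct that is already ground under current bindings
    for idx, c in enumerate(conjuncts):
        resolved = substitute(c, bindings)
        rest = list(conjuncts[:idx]) + list(conjuncts[idx + 1 :])
        if isinstance(resolved, Not) or (
            isinstance(resolved, Compound) and hosts.is_bound(resolved.relation)
        ):
            if is_ground(resolved):
                if _truth(resolved, facts, hosts):
                    yield from _match_conjuncts(rest, facts, hosts, bindings)
                return
            continue  # defer until ground
        # fact pattern: enumerate matches
        for fact in facts:
            b = unify(resolved, fact, bindings)
            if b is not None:
                yield from _match_conjuncts(rest, facts, hosts, b)
        return
    raise TSLError(
        "antecedent has host/negated conjuncts that never become ground: "
        + " ".join(to_sexpr(c) for c in conjuncts)
    )


def forward_chain(
    facts: Iterable[Expression],
    rules: Sequence[InferenceRule],
    hosts: Optional[HostRegistry] = None,
) -> frozenset:
    """Least fixpoint of *rules* over *facts* (ground, function-free).

    Monotone and idempotent: running the closure through the rules again
    adds nothing.
    """
    hosts = hosts or _EMPTY_HOSTS
    closure = set(facts)
    for f in closure:
        if not is_ground(f):
            raise TSLError(f"fact is not ground: {to_sexpr(f)}")
    changed = True
    while changed:
        changed = False
        for rule in rules:
            new: list[Expression] = []
            for b in _match_conjuncts(_conjuncts(rule.antecedent), closure, hosts, {}):
                derived = substitute(rule.consequent, b)
                if not is_ground(derived):
                    raise TSLError(f"rule {rule.name} derived non-ground fact")
                for part in _conjuncts(derived):
                    if part not in closure:
                        new.append(part)
            if new:
                closure.update(new)
                changed = True
    return frozenset(closure)


_rename_counter = itertools.count()


def _rename(rule: InferenceRule) -> InferenceRule:
    n = next(_rename_counter)
    mapping = {v: Variable(f"?_{n}_{v.name[1:]}") for v in variables_of(rule.antecedent)}
    return InferenceRule(
        rule.name, substitute(rule.antecedent, mapping), substitute(rule.consequent, mapping)
    )


@dataclass
class ProofResult:
    bindings: list
    truncated: bool = False


def _canonical_pattern(expr: Expression) -> str:
    """Rename variables by first occurrence so alphabetic variants of the
    same subgoal share one table entry."""
    mapping: dict[Variable, Variable] = {}
    for v in sorted(variables_of(expr), key=lambda v: v.name):
        mapping.setdefault(v, Variable(f"?_{len(mapping)}"))
    return to_sexpr(substitute(expr, mapping))


def backward_chain(
    goal: Expression,
    facts: Iterable[Expression],
    rules: Sequence[InferenceRule],
    hosts: Optional[HostRegistry] = None,
    max_depth: int = 32,
) -> ProofResult:
    """Goal-directed proof search with answer tabling.

    Subgoal answers are memoized per canonical pattern and iterated to a
    fixpoint, so the search is complete for the function-free language and
    terminates even under recursive rules; *max_depth* additionally bounds
    subgoal nesting (``truncated`` reports whether the bound ever cut a
    branch).  Returns every distinct binding of the goal's variables under
    which the goal is provable.
    """
    hosts = hosts or _EMPTY_HOSTS
    fact_set = set(facts)
    truncated = [False]
    goal_vars = variables_of(goal)
    tables: dict[str, set] = {}  # canonical atom pattern -> ground answers

    def solve_atom(pattern: Compound, depth: int, done: set) -> set:
        key = _canonical_pattern(pattern)
        existing = tables.setdefault(key, set())
        if key in done:
            return existing
        done.add(key)
        if depth > max_depth:
            truncated[0] = True
            return existing
        for fact in fact_set:
            if unify(pattern, fact) is not None:
                existing.add(fact)
        for rule in rules:
            fresh = _rename(rule)
            for part in _conjuncts(fresh.consequent):
                b0 = unify(part, pattern)
                if b0 is None:
                    continue
                for b in gen_conjuncts(_conjuncts(fresh.antecedent), b0, depth + 1, done):
                    inst = substitute(part, b)
                    if is_ground(inst) and isinstance(inst, Compound):
                        existing.add(inst)
        return existing

    def gen_conjuncts(conjuncts, bindings: Bindings, depth: int, done: set) -> Iterator[Bindings]:
        if not conjuncts:
            yield bindings
            return
        for idx, c in enumerate(conjuncts):
            g = substitute(c, bindings)
            rest = list(conjuncts[:idx]) + list(conjuncts[idx + 1 :])
            if isinstance(g, And):
                yield from gen_conjuncts(list(g.args) + rest, bindings, depth, done)
                return
            if isinstance(g, Or):
                for alt in g.args:
                    yield from gen_conjuncts([alt] + rest, bindings, depth, done)
                return
            if isinstance(g, Not) or (
                isinstance(g, Compound) and hosts.is_bound(g.relation)
            ):
                # negation consults the *stated* facts plus host relations;
                # host calls need ground arguments -- defer until bound
                if is_ground(g):
                    if _truth(g, fact_set, hosts):
                        yield from gen_conjuncts(rest, bindings, depth, done)
                    return
                continue
            if isinstance(g, Compound):
                for answer in sorted(solve_atom(g, depth, done), key=to_sexpr):
                    b = unify(g, answer, bindings)
                    if b is not None:
                        yield from gen_conjuncts(rest, b, depth, done)
                return
            # bare atom goal: provable iff asserted
            if g in fact_set:
                yield from gen_conjuncts(rest, bindings, depth, done)
            return
        raise TSLError("goal conjuncts never become ground: " + " ".join(map(to_sexpr, conjuncts)))

    # iterate whole-query passes until no table grows (mutually recursive
    # subgoals see each other's partial answers and converge to the fixpoint)
    while True:
        sizes = {k: len(v) for k, v in tables.items()}
        results = list(gen_conjuncts([goal], {}, 0, set()))
        if {k: len(v) for k, v in tables.items()} == sizes:
            break

    seen: set[tuple] = set()
    out: list[Bindings] = []
    for b in results:
        resolved = {v: substitute(v, b) for v in goal_vars}
        key = tuple(sorted((v.name, to_sexpr(e)) for v, e in resolved.items()))
        if key not in seen:
            seen.add(key)
            out.append(resolved)
    return ProofResult(out, truncated[0])
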