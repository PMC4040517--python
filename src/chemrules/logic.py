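"""Terms, atoms, rules and programs for nonmonotonic existential rules.

The vocabulary is the one used for structure-based chemical classification:
constants name individual molecules, variables range over molecules and
atoms, and functional (skolem) terms ``f_i@mol(x)`` stand for the i-th atom
node of the description graph of molecule predicate ``mol``.  Rules have a
positive body (which may carry inequalities), a negation-as-failure body and
a single head atom; multi-atom heads are normalised to one rule per conjunct
at construction time.

A small textual dialect (documented in ``docs/rule_dialect.md``) serialises
rules and facts; ``parse_rules`` / ``format_rules`` round-trip it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

__all__ = [
    "Variable",
    "Constant",
    "FunctionSymbol",
    "FunctionalTerm",
    "Term",
    "Atom",
    "Inequality",
    "Rule",
    "Program",
    "StableModel",
    "SafetyReport",
    "check_safety",
    "make_rules",
    "parse_rules",
    "format_rules",
    "format_atom",
    "format_term",
    "DialectSyntaxError",
]


# ---------------------------------------------------------------------------
# Terms


@dataclass(frozen=True, slots=True)
class Variable:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Constant:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class FunctionSymbol:
    """Skolem function symbol ``f_<index>`` private to one molecule predicate.

    Distinct molecules use distinct symbols, so ground functional terms of
    two molecules can never be syntactically equal (unique name assumption).
    """

    molecule: str
    index: int

    def __str__(self) -> str:
        return f"f{self.index}@{self.molecule}"


@dataclass(frozen=True, slots=True)
class FunctionalTerm:
    fsym: FunctionSymbol
    arg: "Term"

    def __str__(self) -> str:
        return f"{self.fsym}({self.arg})"


Term = Union[Variable, Constant, FunctionalTerm]


def term_variables(t: Term) -> Iterator[Variable]:
    if isinstance(t, Variable):
        yield t
    elif isinstance(t, FunctionalTerm):
        yield from term_variables(t.arg)


def term_is_ground(t: Term) -> bool:
    if isinstance(t, Variable):
        return False
    if isinstance(t, FunctionalTerm):
        return term_is_ground(t.arg)
    return True


def term_depth(t: Term) -> int:
    """Nesting depth of functional symbols (constants/variables are 0)."""
    d = 0
    while isinstance(t, FunctionalTerm):
        d += 1
        t = t.arg
    return d


def term_contains_fsym(t: Term, fsym: FunctionSymbol) -> bool:
    while isinstance(t, FunctionalTerm):
        if t.fsym == fsym:
            return True
        t = t.arg
    return False


def substitute_term(t: Term, subst: dict) -> Term:
    if isinstance(t, Variable):
        return subst.get(t, t)
    if isinstance(t, FunctionalTerm):
        return FunctionalTerm(t.fsym, substitute_term(t.arg, subst))
    return t


# ---------------------------------------------------------------------------
# Atoms


MAX_ARITY = 4


@dataclass(frozen=True, slots=True)
class Atom:
    """``predicate(t1, ..., tk)`` with 1 <= k <= 4.

    Unary atoms type individuals (``o(f1@asc(a))``), binary atoms relate
    them (``single(x, y)``); higher arities appear only in the internal
    cyclicity encoding.
    """

    predicate: str
    args: tuple[Term, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.args) <= MAX_ARITY:
            raise ValueError(
                f"atom {self.predicate}/{len(self.args)}: arity must be 1..{MAX_ARITY}"
            )

    @property
    def arity(self) -> int:
        return len(self.args)

    def variables(self) -> Iterator[Variable]:
        for a in self.args:
            yield from term_variables(a)

    def is_ground(self) -> bool:
        return all(term_is_ground(a) for a in self.args)

    def is_function_free(self) -> bool:
        return not any(isinstance(a, FunctionalTerm) for a in self.args)

    def substitute(self, subst: dict) -> "Atom":
        return Atom(self.predicate, tuple(substitute_term(a, subst) for a in self.args))

    def __str__(self) -> str:
        return format_atom(self)


@dataclass(frozen=True, slots=True)
class Inequality:
    """``left != right`` under the unique name assumption: the inequality
    holds iff the two ground terms are syntactically distinct."""

    left: Term
    right: Term

    def variables(self) -> Iterator[Variable]:
        yield from term_variables(self.left)
        yield from term_variables(self.right)

    def substitute(self, subst: dict) -> "Inequality":
        return Inequality(substitute_term(self.left, subst), substitute_term(self.right, subst))

    def holds(self) -> bool:
        return self.left != self.right

    def __str__(self) -> str:
        return f"{format_term(self.left)} != {format_term(self.right)}"


# ---------------------------------------------------------------------------
# Rules and programs


@dataclass(frozen=True)
class SafetyReport:
    ok: bool
    unsafe_variables: frozenset[Variable] = frozenset()
    message: str = ""


@dataclass(frozen=True)
class Rule:
    """One nonmonotonic existential rule with a single head atom.

    ``positive_body`` holds the ordinary (non-inequality) positive atoms;
    inequalities live in ``inequalities``; ``negative_body`` atoms are
    interpreted as negation-as-failure and must be function-free.  The head
    is the only place functional terms may introduce fresh individuals.
    """

    positive_body: frozenset[Atom]
    negative_body: frozenset[Atom]
    head: Atom
    inequalities: frozenset[Inequality] = frozenset()

    @staticmethod
    def make(
        positive: Iterable[Union[Atom, Inequality]],
        negative: Iterable[Atom],
        head: Atom,
    ) -> "Rule":
        """Build a rule, sorting inequalities out of the positive body."""
        pos, ineqs = [], []
        for a in positive:
            (ineqs if isinstance(a, Inequality) else pos).append(a)
        return Rule(frozenset(pos), frozenset(negative), head, frozenset(ineqs))

    def body_variables(self) -> set[Variable]:
        vs: set[Variable] = set()
        for a in self.positive_body:
            vs.update(a.variables())
        return vs

    def is_fact(self) -> bool:
        return not self.positive_body and not self.negative_body and not self.inequalities

    def __str__(self) -> str:
        return format_rule(self)


def check_safety(rule: Rule) -> SafetyReport:
    """Standard safety for rules with negation and inequalities.

    Every variable occurring in the head, in a negated atom or in an
    inequality must also occur in a positive non-inequality body atom, and
    negated atoms must be function-free.
    """
    positive_vars = rule.body_variables()
    needed: set[Variable] = set(rule.head.variables())
    for a in rule.negative_body:
        needed.update(a.variables())
    for iq in rule.inequalities:
        needed.update(iq.variables())
    unsafe = needed - positive_vars
    problems = []
    if unsafe:
        names = ", ".join(sorted(v.name for v in unsafe))
        problems.append(f"unsafe variables: {names}")
    not_ff = [a for a in rule.negative_body if not a.is_function_free()]
    if not_ff:
        problems.append("negated atoms must be function-free: " + "; ".join(map(str, not_ff)))
    if problems:
        return SafetyReport(False, frozenset(unsafe), "; ".join(problems))
    return SafetyReport(True)


def make_rules(
    positive: Iterable[Union[Atom, Inequality]],
    negative: Iterable[Atom],
    heads: Iterable[Atom],
) -> list[Rule]:
    """Normalise a conjunctive head into one rule per head conjunct."""
    positive = list(positive)
    negative = list(negative)
    return [Rule.make(positive, negative, h) for h in heads]


class UnsafeRuleError(ValueError):
    pass


@dataclass(frozen=True)
class Program:
    """A set of safe rules plus a set of ground seed facts."""

    rules: frozenset[Rule]
    facts: frozenset[Atom]

    def __post_init__(self) -> None:
        for f in self.facts:
            if not f.is_ground():
                raise ValueError(f"program fact is not ground: {f}")
        for r in self.rules:
            rep = check_safety(r)
            if not rep.ok:
                raise UnsafeRuleError(f"unsafe rule {r}: {rep.message}")

    @staticmethod
    def make(rules: Iterable[Rule], facts: Iterable[Atom] = ()) -> "Program":
        return Program(frozenset(rules), frozenset(facts))

    def predicates(self) -> set[str]:
        preds = {f.predicate for f in self.facts}
        for r in self.rules:
            preds.add(r.head.predicate)
            preds.update(a.predicate for a in r.positive_body)
            preds.update(a.predicate for a in r.negative_body)
        return preds


@dataclass(frozen=True)
class StableModel:
    """The set of ground facts derived from a program (rule-closed, founded)."""

    facts: frozenset[Atom]

    def __contains__(self, atom: Atom) -> bool:
        return atom in self.facts

    def __len__(self) -> int:
        return len(self.facts)

    def with_predicate(self, predicate: str) -> list[Atom]:
        return sorted(
            (f for f in self.facts if f.predicate == predicate), key=format_atom
        )

    def sorted_facts(self) -> list[Atom]:
        return sorted(self.facts, key=lambda a: (a.predicate, format_atom(a)))


# ---------------------------------------------------------------------------
# Textual dialect
#
#   rule  := head ":-" body "."         (":-" may be written "->" reversed)
#   fact  := atom "."
#   body  := literal ("," literal)*
#   literal := "not " atom | term "!=" term | atom
#   atom  := NAME "(" term ("," term)* ")"
#   term  := VARIABLE | NAME | "f" INT "@" NAME "(" term ")"
#
# Variables start with an upper-case letter, predicates/constants with a
# lower-case letter.  One statement per line; "%" starts a comment.


class DialectSyntaxError(SyntaxError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>%[^\n]*)
  | (?P<fsym>f\d+@[a-z][A-Za-z0-9_]*)
  | (?P<name>[a-z][A-Za-z0-9_]*)
  | (?P<var>[A-Z][A-Za-z0-9_]*)
  | (?P<neq>!=)
  | (?P<arrow>:-|->)
  | (?P<punct>[(),.])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int, int]]:
    tokens = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DialectSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind not in ("ws", "comment"):
            tokens.append((kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(("eof", "", line, col))
    return tokens


class _RuleParser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self, kind=None, value=None):
        tok = self.tokens[self.i]
        if kind is not None and tok[0] != kind or (value is not None and tok[1] != value):
            expected = value or kind
            raise DialectSyntaxError(f"expected {expected}, found {tok[1]!r}", tok[2], tok[3])
        self.i += 1
        return tok

    def error(self, msg):
        tok = self.peek()
        raise DialectSyntaxError(msg, tok[2], tok[3])

    # grammar ---------------------------------------------------------------

    def parse_program(self) -> Program:
        rules, facts = [], []
        while self.peek()[0] != "eof":
            stmt = self.parse_statement()
            if isinstance(stmt, Rule):
                rules.append(stmt)
            else:
                facts.append(stmt)
        return Program.make(rules, facts)

    def parse_statement(self):
        first = self.parse_literal()
        kind = self.peek()[0]
        if kind == "punct" and self.peek()[1] == ".":
            self.next()
            if not isinstance(first, Atom):
                self.error("a fact must be a plain atom")
            if not first.is_ground():
                self.error(f"fact {first} is not ground")
            return first
        if kind == "arrow" and self.peek()[1] == ":-":
            # head :- body .
            if not isinstance(first, Atom):
                self.error("rule head must be a plain atom")
            self.next()
            body = self.parse_body()
            self.next("punct", ".")
            return self._build_rule(body, first)
        if kind == "punct" and self.peek()[1] == ",":
            # body -> head .  (body continues)
            body = [first]
            while self.peek()[1] == ",":
                self.next()
                body.append(self.parse_literal())
            self.next("arrow", "->")
            head = self.parse_literal()
            if not isinstance(head, Atom):
                self.error("rule head must be a plain atom")
            self.next("punct", ".")
            return self._build_rule(body, head)
        if kind == "arrow" and self.peek()[1] == "->":
            self.next()
            head = self.parse_literal()
            if not isinstance(head, Atom):
                self.error("rule head must be a plain atom")
            self.next("punct", ".")
            return self._build_rule([first], head)
        self.error("expected '.', ',', ':-' or '->'")

    def _build_rule(self, body, head) -> Rule:
        positive, negative = [], []
        for lit in body:
            if isinstance(lit, tuple) and lit[0] == "not":
                negative.append(lit[1])
            else:
                positive.append(lit)
        rule = Rule.make(positive, negative, head)
        rep = check_safety(rule)
        if not rep.ok:
            raise ValueError(f"unsafe rule {rule}: {rep.message}")
        return rule

    def parse_body(self):
        body = [self.parse_literal()]
        while self.peek()[1] == ",":
            self.next()
            body.append(self.parse_literal())
        return body

    def parse_literal(self):
        kind, value, line, col = self.peek()
        if kind == "name" and value == "not":
            self.next()
            atom = self.parse_atom_or_term()
            if not isinstance(atom, Atom):
                self.error("'not' must be applied to an atom")
            return ("not", atom)
        item = self.parse_atom_or_term()
        if self.peek()[0] == "neq":
            self.next()
            right = self.parse_term()
            if isinstance(item, Atom):
                self.error("left side of '!=' must be a term")
            return Inequality(item, right)
        if not isinstance(item, Atom):
            self.error("expected an atom or inequality")
        return item

    def parse_atom_or_term(self):
        kind, value, line, col = self.peek()
        if kind == "name":
            self.next()
            if self.peek()[1] == "(":
                self.next()
                args = [self.parse_term()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.parse_term())
                self.next("punct", ")")
                return Atom(value, tuple(args))
            return Constant(value)
        return self.parse_term()

    def parse_term(self) -> Term:
        kind, value, line, col = self.peek()
        if kind == "var":
            self.next()
            return Variable(value)
        if kind == "fsym":
            self.next()
            idx, mol = value[1:].split("@")
            self.next("punct", "(")
            arg = self.parse_term()
            self.next("punct", ")")
            return FunctionalTerm(FunctionSymbol(mol, int(idx)), arg)
        if kind == "name":
            self.next()
            return Constant(value)
        self.error("expected a term")


def parse_rules(text: str) -> Program:
    """Parse the textual rule dialect into a :class:`Program`."""
    return _RuleParser(text).parse_program()


def format_term(t: Term) -> str:
    if isinstance(t, FunctionalTerm):
        return f"f{t.fsym.index}@{t.fsym.molecule}({format_term(t.arg)})"
    return t.name


def format_atom(a: Atom) -> str:
    return f"{a.predicate}({', '.join(format_term(t) for t in a.args)})"


def format_rule(r: Rule) -> str:
    body = sorted(format_atom(a) for a in r.positive_body)
    body += sorted(str(iq) for iq in r.inequalities)
    body += sorted("not " + format_atom(a) for a in r.negative_body)
    if not body:
        return f"{format_atom(r.head)}."
    return f"{format_atom(r.head)} :- {', '.join(body)}."


def format_rules(program: Program) -> str:
    """Deterministic (sorted) rendering, so compiled KBs are byte-reproducible."""
    lines = sorted(format_atom(f) + "." for f in program.facts)
    lines += sorted(format_rule(r) for r in program.rules)
    return "\n".join(lines) + ("\n" if lines else "")
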