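"""Surface syntax for chemical-class axioms, and its lowering to rules.

The surface syntax lets a domain expert write class definitions without
first-order notation, e.g.::

    alkane SuperClassOf saturated AND hydroCarbon AND NOT cyclic
    carbonEntity SuperClassOf hasAtom SOME c
    exactly2Carbons SuperClassOf molecule AND hasAtom EXACTLY 2 c
    ascorbicAcid SubClassOf molecule AND ( hasAtom SOME Graph ( Nodes ( ... ) Edges ( ... ) ) )

Keywords are case-sensitive and whitespace-separated
(``SubClassOf SuperClassOf SuperPropertyOf AND OR NOT SOME ONLY EXACTLY
Graph GraphNL Nodes Edges DisjointNodes``); ``#`` starts a comment; an
axiom ends at the next line that starts a new axiom (name followed by an
axiom keyword) at parenthesis depth zero.  ``GraphNL`` is required whenever
a node carries a NOT-label or a DisjointNodes block is present.  The full
grammar is documented in ``docs/surface_syntax.md``.

Lowering (:func:`lower_axiom`) is deterministic, auxiliary predicate names
are stable across runs, and each construct maps to rules as follows:
``SubClassOf`` with a graph filler yields skolemized structure rules;
``SuperClassOf`` yields recognition rules (graph nodes → positive body,
NOT-labels → negated atoms, DisjointNodes → inequalities); ``ONLY`` goes
through a ``not<Class>`` violation predicate; ``EXACTLY n`` goes through
``atLeast<n>``/``atLeast<n+1>`` predicates combined with negation;
``SuperPropertyOf`` with OR yields one inclusion rule per disjunct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .logic import (
    Atom,
    FunctionSymbol,
    FunctionalTerm,
    Inequality,
    Rule,
    Variable,
    make_rules,
)

__all__ = [
    "SurfaceAxiom",
    "ClassName",
    "And",
    "Or",
    "Not",
    "Some",
    "Only",
    "Exactly",
    "GraphExpr",
    "GraphNode",
    "SurfaceSyntaxError",
    "LoweringError",
    "parse_surface",
    "print_surface",
    "lower_axiom",
    "lower_axioms",
    "KNOWN_SOME_CLASSES",
    "COUNT_ALIASES",
]


KEYWORDS = frozenset(
    """SubClassOf SuperClassOf SuperPropertyOf AND OR NOT SOME ONLY EXACTLY
    Graph GraphNL Nodes Edges DisjointNodes""".split()
)
AXIOM_KINDS = ("SubClassOf", "SuperClassOf", "SuperPropertyOf")

# Definitional equivalences the lowering may reuse: role SOME filler ⇔ class.
# Used when negating an ONLY filler, e.g. `hasAtom ONLY ( NOT c )` becomes
# `not carbonEntity(x)` instead of a synthesized auxiliary.
KNOWN_SOME_CLASSES: dict[tuple[str, str], str] = {("hasAtom", "c"): "carbonEntity"}

# Element predicate → counting-aux name fragment (atLeast2Carbons etc.).
COUNT_ALIASES: dict[str, str] = {
    "c": "Carbon",
    "o": "Oxygen",
    "h": "Hydrogen",
    "n": "Nitrogen",
    "s": "Sulfur",
    "p": "Phosphorus",
}


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class ClassName:
    name: str


@dataclass(frozen=True)
class And:
    parts: tuple


@dataclass(frozen=True)
class Or:
    parts: tuple


@dataclass(frozen=True)
class Not:
    expr: object


@dataclass(frozen=True)
class Some:
    role: str
    filler: object


@dataclass(frozen=True)
class Only:
    role: str
    filler: object


@dataclass(frozen=True)
class Exactly:
    role: str
    n: int
    filler: object


@dataclass(frozen=True)
class GraphNode:
    index: int
    labels: tuple[str, ...]
    not_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class GraphExpr:
    nl: bool  # True for GraphNL
    nodes: tuple[GraphNode, ...]
    edges: tuple[tuple[int, int, str], ...]
    disjoint: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class SurfaceAxiom:
    kind: str  # SubClassOf | SuperClassOf | SuperPropertyOf
    left: str
    right: object


class SurfaceSyntaxError(SyntaxError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class LoweringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parsing


_TOKEN_RE = re.compile(
    r"(?P<ws>\s+)|(?P<comment>\#[^\n]*)|(?P<name>[A-Za-z][A-Za-z0-9_]*)"
    r"|(?P<int>\d+)|(?P<punct>[(),])"
)


def _tokenize(text: str):
    tokens = []
    pos, line, col = 0, 1, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SurfaceSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind, value = m.lastgroup, m.group()
        if kind not in ("ws", "comment"):
            tokens.append((kind, value, line, col))
        nl = value.count("\n")
        if nl:
            line += nl
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(("eof", "", line, col))
    return tokens


class _SurfaceParser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self, ahead: int = 0):
        return self.tokens[min(self.i + ahead, len(self.tokens) - 1)]

    def next(self, value: Optional[str] = None):
        tok = self.tokens[self.i]
        if value is not None and tok[1] != value:
            raise SurfaceSyntaxError(f"expected {value!r}, found {tok[1]!r}", tok[2], tok[3])
        self.i += 1
        return tok

    def error(self, msg: str):
        tok = self.peek()
        raise SurfaceSyntaxError(msg, tok[2], tok[3])

    def at_axiom_start(self) -> bool:
        return (
            self.peek()[0] == "name"
            and self.peek()[1] not in KEYWORDS
            and self.peek(1)[1] in AXIOM_KINDS
        )

    def parse_axioms(self) -> list[SurfaceAxiom]:
        axioms = []
        while self.peek()[0] != "eof":
            if not self.at_axiom_start():
                self.error("expected an axiom: NAME followed by "
                           "SubClassOf/SuperClassOf/SuperPropertyOf")
            left = self.next()[1]
            kind = self.next()[1]
            right = self.parse_expr()
            axioms.append(SurfaceAxiom(kind, left, right))
        return axioms

    def parse_expr(self):
        parts = [self.parse_conj()]
        while self.peek()[1] == "OR":
            self.next()
            parts.append(self.parse_conj())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_conj(self):
        parts = [self.parse_unary()]
        while self.peek()[1] == "AND":
            self.next()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self):
        if self.peek()[1] == "NOT":
            self.next()
            return Not(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self):
        kind, value, line, col = self.peek()
        if value == "(":
            self.next()
            inner = self.parse_expr()
            self.next(")")
            return inner
        if value in ("Graph", "GraphNL"):
            return self.parse_graph()
        if kind == "name":
            if value in KEYWORDS:
                self.error(f"keyword {value!r} cannot start an expression")
            name = self.next()[1]
            follow = self.peek()[1]
            if follow == "SOME":
                self.next()
                return Some(name, self.parse_filler())
            if follow == "ONLY":
                self.next()
                return Only(name, self.parse_filler())
            if follow == "EXACTLY":
                self.next()
                ntok = self.next()
                if ntok[0] != "int":
                    raise SurfaceSyntaxError("EXACTLY needs a number", ntok[2], ntok[3])
                return Exactly(name, int(ntok[1]), self.parse_filler())
            return ClassName(name)
        self.error("expected a class expression")

    def parse_filler(self):
        # A filler is a name, a (parenthesized) expression, a graph, or NOT-
        # prefixed; it never extends into a following AND/OR at this level.
        kind, value, _, _ = self.peek()
        if value == "NOT":
            self.next()
            return Not(self.parse_filler())
        if value == "(":
            self.next()
            inner = self.parse_expr()
            self.next(")")
            return inner
        if value in ("Graph", "GraphNL"):
            return self.parse_graph()
        if kind == "name" and value not in KEYWORDS:
            return ClassName(self.next()[1])
        self.error("expected a filler")

    def parse_graph(self) -> GraphExpr:
        gkind = self.next()[1]
        nl = gkind == "GraphNL"
        gline, gcol = self.tokens[self.i - 1][2], self.tokens[self.i - 1][3]
        self.next("(")
        nodes: list[GraphNode] = []
        disjoint: list[tuple[int, int]] = []
        if self.peek()[1] == "Nodes":
            self.next()
            self.next("(")
            if self.peek()[1] != ")":
                nodes.append(self.parse_node())
                while self.peek()[1] == ",":
                    self.next()
                    nodes.append(self.parse_node())
            self.next(")")
        if self.peek()[1] == "DisjointNodes":
            self.next()
            self.next("(")
            if self.peek()[1] == "(":
                while self.peek()[1] == "(":
                    self.next()
                    i = int(self.next()[1])
                    self.next(",")
                    j = int(self.next()[1])
                    self.next(")")
                    disjoint.append((i, j))
                    if self.peek()[1] == ",":
                        self.next()
            else:
                i = int(self.next()[1])
                self.next(",")
                j = int(self.next()[1])
                disjoint.append((i, j))
            self.next(")")
        if self.peek()[1] != "Edges":
            self.error("expected an Edges block")
        self.next()
        self.next("(")
        edges: list[tuple[int, int, str]] = []
        if self.peek()[1] != ")":
            edges.append(self.parse_edge())
            while self.peek()[1] == ",":
                self.next()
                edges.append(self.parse_edge())
        self.next(")")
        self.next(")")
        if not nl and (disjoint or any(n.not_labels for n in nodes)):
            raise SurfaceSyntaxError(
                "Graph cannot carry NOT-labels or DisjointNodes; use GraphNL",
                gline,
                gcol,
            )
        return GraphExpr(nl, tuple(nodes), tuple(edges), tuple(disjoint))

    def parse_node(self) -> GraphNode:
        tok = self.next()
        if tok[0] != "int":
            raise SurfaceSyntaxError("node entry must start with an index", tok[2], tok[3])
        index = int(tok[1])
        labels: list[str] = []
        not_labels: list[str] = []
        while True:
            kind, value, _, _ = self.peek()
            if value == "NOT":
                self.next()
                lab = self.next()
                if lab[0] != "name" or lab[1] in KEYWORDS:
                    raise SurfaceSyntaxError("expected a label after NOT", lab[2], lab[3])
                not_labels.append(lab[1])
            elif kind == "name" and value not in KEYWORDS:
                labels.append(self.next()[1])
            else:
                break
        return GraphNode(index, tuple(labels), tuple(not_labels))

    def parse_edge(self) -> tuple[int, int, str]:
        i = self.next()
        j = self.next()
        lab = self.next()
        if i[0] != "int" or j[0] != "int":
            raise SurfaceSyntaxError("edge must be INT INT LABEL", i[2], i[3])
        if lab[0] != "name" or lab[1] in KEYWORDS:
            raise SurfaceSyntaxError("edge must end with a label", lab[2], lab[3])
        return (int(i[1]), int(j[1]), lab[1])


def parse_surface(text: str) -> list[SurfaceAxiom]:
    """Parse surface-syntax text into a list of axioms."""
    return _SurfaceParser(text).parse_axioms()


# ---------------------------------------------------------------------------
# Printing (canonical; parse ∘ print is the identity on ASTs)


def _print_expr(e, *, top: bool = False) -> str:
    if isinstance(e, ClassName):
        return e.name
    if isinstance(e, And):
        return " AND ".join(_print_part(p) for p in e.parts)
    if isinstance(e, Or):
        return " OR ".join(_print_part(p) for p in e.parts)
    if isinstance(e, Not):
        return "NOT " + _print_part(e.expr)
    if isinstance(e, Some):
        return f"{e.role} SOME {_print_filler(e.filler)}"
    if isinstance(e, Only):
        return f"{e.role} ONLY {_print_filler(e.filler)}"
    if isinstance(e, Exactly):
        return f"{e.role} EXACTLY {e.n} {_print_filler(e.filler)}"
    if isinstance(e, GraphExpr):
        return _print_graph(e)
    raise TypeError(f"not a surface expression: {e!r}")


def _print_part(e) -> str:
    if isinstance(e, (And, Or)):
        return f"( {_print_expr(e)} )"
    return _print_expr(e)


def _print_filler(e) -> str:
    if isinstance(e, (ClassName, GraphExpr)):
        return _print_expr(e)
    if isinstance(e, Not) and isinstance(e.expr, ClassName):
        return f"( NOT {e.expr.name} )"
    return f"( {_print_expr(e)} )"


def _print_graph(g: GraphExpr) -> str:
    parts = [("GraphNL" if g.nl else "Graph"), "("]
    if g.nodes:
        entries = []
        for n in g.nodes:
            entry = [str(n.index), *n.labels]
            for nl in n.not_labels:
                entry += ["NOT", nl]
            entries.append(" ".join(entry))
        parts += ["Nodes", "(", " , ".join(entries), ")"]
    if g.disjoint:
        if len(g.disjoint) == 1:
            i, j = g.disjoint[0]
            parts += ["DisjointNodes", "(", f"{i} , {j}", ")"]
        else:
            pairs = " , ".join(f"( {i} , {j} )" for i, j in g.disjoint)
            parts += ["DisjointNodes", "(", pairs, ")"]
    entries = " , ".join(f"{i} {j} {lab}" for i, j, lab in g.edges)
    parts += ["Edges", "(", entries, ")", ")"]
    return " ".join(p for p in parts if p)


def print_surface(axioms: Union[SurfaceAxiom, Iterable[SurfaceAxiom]]) -> str:
    if isinstance(axioms, SurfaceAxiom):
        axioms = [axioms]
    return "\n".join(f"{a.left} {a.kind} {_print_expr(a.right, top=True)}" for a in axioms)


# ---------------------------------------------------------------------------
# Lowering


def _flatten_and(e) -> list:
    if isinstance(e, And):
        out = []
        for p in e.parts:
            out.extend(_flatten_and(p))
        return out
    return [e]


def _cap(name: str) -> str:
    return name[0].upper() + name[1:]


class _VarPool:
    def __init__(self) -> None:
        self.used: set[str] = set()

    def fresh(self, hint: int) -> Variable:
        k = hint
        while f"Y{k}" in self.used:
            k += 1
        self.used.add(f"Y{k}")
        return Variable(f"Y{k}")


def _uses_molecule_root(conjuncts: list) -> bool:
    # The root individual is an atom (not a molecule) exactly when the
    # axiom talks about the root's own bonds, as in middleOxygen; such
    # classes get hasAtom guards binding all atom variables to a common
    # molecule.  Everything else is a molecule-level class.
    return not any(
        isinstance(c, (Some, Only, Exactly)) and c.role == "bond" for c in conjuncts
    )


def lower_axiom(
    ax: SurfaceAxiom,
    *,
    known_some_classes: Optional[dict[tuple[str, str], str]] = None,
    count_aliases: Optional[dict[str, str]] = None,
) -> set[Rule]:
    """Translate one surface axiom into its set of nonmonotonic rules."""
    known = KNOWN_SOME_CLASSES if known_some_classes is None else known_some_classes
    aliases = COUNT_ALIASES if count_aliases is None else count_aliases

    if ax.kind == "SuperPropertyOf":
        return _lower_superproperty(ax)
    if ax.kind == "SubClassOf":
        return _lower_structure(ax)
    if ax.kind == "SuperClassOf":
        return _lower_recognition(ax, known, aliases)
    raise LoweringError(f"unknown axiom kind {ax.kind!r}")


def lower_axioms(axioms: Iterable[SurfaceAxiom], **kwargs) -> set[Rule]:
    rules: set[Rule] = set()
    for ax in axioms:
        rules |= lower_axiom(ax, **kwargs)
    return rules


def _lower_superproperty(ax: SurfaceAxiom) -> set[Rule]:
    right = ax.right
    parts = right.parts if isinstance(right, Or) else (right,)
    rules = set()
    x, y = Variable("X"), Variable("Y")
    for p in parts:
        if not isinstance(p, ClassName):
            raise LoweringError("SuperPropertyOf expects a property name or an OR of names")
        rules.add(Rule.make([Atom(p.name, (x, y))], [], Atom(ax.left, (x, y))))
    return rules


def _lower_structure(ax: SurfaceAxiom) -> set[Rule]:
    """``C SubClassOf ...`` — unfold into skolemized structure rules."""
    x = Variable("X")
    body = [Atom(ax.left, (x,))]
    heads: list[Atom] = []
    for c in _flatten_and(ax.right):
        if isinstance(c, ClassName):
            heads.append(Atom(c.name, (x,)))
        elif isinstance(c, Some) and isinstance(c.filler, GraphExpr):
            g = c.filler
            if any(n.not_labels for n in g.nodes) or g.disjoint:
                raise LoweringError(
                    "NOT-labels and DisjointNodes cannot be asserted in a "
                    "SubClassOf (structure) axiom"
                )
            skolem = {
                n.index: FunctionalTerm(FunctionSymbol(ax.left, n.index), x)
                for n in g.nodes
            }
            for n in sorted(g.nodes, key=lambda n: n.index):
                heads.append(Atom(c.role, (x, skolem[n.index])))
                for lab in sorted(n.labels):
                    heads.append(Atom(lab, (skolem[n.index],)))
            for (i, j, lab) in sorted(g.edges):
                if i not in skolem or j not in skolem:
                    raise LoweringError(f"edge ({i},{j}) references an undeclared node")
                heads.append(Atom(lab, (skolem[i], skolem[j])))
                heads.append(Atom(lab, (skolem[j], skolem[i])))
        else:
            raise LoweringError(
                f"unsupported construct in SubClassOf axiom: {type(c).__name__}"
            )
    return set(make_rules(body, [], heads))


def _lower_recognition(
    ax: SurfaceAxiom,
    known: dict[tuple[str, str], str],
    aliases: dict[str, str],
) -> set[Rule]:
    right = ax.right
    if isinstance(right, Or):
        rules = set()
        x = Variable("X")
        for p in right.parts:
            if not isinstance(p, ClassName):
                raise LoweringError("a top-level OR must be a disjunction of class names")
            rules.add(Rule.make([Atom(p.name, (x,))], [], Atom(ax.left, (x,))))
        return rules
    if isinstance(right, ClassName):
        x = Variable("X")
        return {Rule.make([Atom(right.name, (x,))], [], Atom(ax.left, (x,)))}

    conjuncts = _flatten_and(right)
    molecule_level = _uses_molecule_root(conjuncts)
    pool = _VarPool()
    if molecule_level:
        root = Variable("X")
    else:
        root = pool.fresh(1)

    positive: list[Atom] = []
    negative: list[Atom] = []
    ineqs: list[Inequality] = []
    aux_rules: set[Rule] = set()
    atom_vars: list[Variable] = []  # atom-node variables (for atom-level wrap)
    exactly: Optional[Exactly] = None

    def lower_graph_filler(role: str, g: GraphExpr):
        node_var = {n.index: pool.fresh(n.index) for n in sorted(g.nodes, key=lambda n: n.index)}
        for i, j in g.disjoint:
            for k in (i, j):
                if k not in node_var:
                    node_var[k] = pool.fresh(k)
        declared = {n.index for n in g.nodes}
        for i, j, _ in g.edges:
            if i not in node_var or j not in node_var:
                raise LoweringError(f"edge ({i},{j}) references an undeclared node")
        for idx in sorted(node_var):
            positive.append(Atom(role, (root, node_var[idx])))
            atom_vars.append(node_var[idx])
        for n in sorted(g.nodes, key=lambda n: n.index):
            for lab in n.labels:
                positive.append(Atom(lab, (node_var[n.index],)))
            for lab in n.not_labels:
                negative.append(Atom(lab, (node_var[n.index],)))
        for (i, j, lab) in g.edges:
            positive.append(Atom(lab, (node_var[i], node_var[j])))
        for (i, j) in g.disjoint:
            ineqs.append(Inequality(node_var[i], node_var[j]))

    for c in conjuncts:
        if isinstance(c, ClassName):
            positive.append(Atom(c.name, (root,)))
        elif isinstance(c, Not):
            if not isinstance(c.expr, ClassName):
                raise LoweringError("NOT may only be applied to a class name here")
            negative.append(Atom(c.expr.name, (root,)))
        elif isinstance(c, Some):
            if isinstance(c.filler, ClassName):
                if molecule_level and c.role == "hasAtom" and not any(
                    isinstance(d, ClassName) and d.name == "molecule" for d in conjuncts
                ):
                    # Domain guard, as in the lowering of `hasAtom SOME c`.
                    positive.insert(0, Atom("molecule", (root,)))
                y = pool.fresh(1)
                positive.append(Atom(c.role, (root, y)))
                positive.append(Atom(c.filler.name, (y,)))
                atom_vars.append(y)
            elif isinstance(c.filler, GraphExpr):
                lower_graph_filler(c.role, c.filler)
            else:
                raise LoweringError("SOME filler must be a class name or a graph")
        elif isinstance(c, Only):
            aux_rules |= _lower_only(ax.left, c, root, negative, known)
        elif isinstance(c, Exactly):
            if exactly is not None:
                raise LoweringError("at most one EXACTLY restriction per axiom")
            exactly = c
        elif isinstance(c, GraphExpr):
            raise LoweringError("a graph must appear as a SOME filler")
        else:
            raise LoweringError(f"unsupported construct: {type(c).__name__}")

    if exactly is not None:
        return aux_rules | _lower_exactly(
            ax.left, exactly, root, positive, negative, ineqs, aliases
        )

    if not molecule_level:
        x = Variable("X")
        guards = [Atom("hasAtom", (x, v)) for v in [root] + atom_vars]
        positive = guards + positive

    head = Atom(ax.left, (root,))
    rule = Rule.make(positive + ineqs, negative, head)
    return aux_rules | {rule}


def _lower_only(
    class_name: str,
    c: Only,
    root: Variable,
    negative: list[Atom],
    known: dict[tuple[str, str], str],
) -> set[Rule]:
    """``role ONLY filler`` via a violation predicate under negation."""
    filler = c.filler
    x, z = Variable("X"), Variable("Z")
    if isinstance(filler, Not) and isinstance(filler.expr, ClassName):
        # ONLY (NOT p): a single positive p-successor violates the axiom;
        # reuse a known `role SOME p` class when one is registered.
        p = filler.expr.name
        known_class = known.get((c.role, p))
        if known_class is not None:
            negative.append(Atom(known_class, (root,)))
            return set()
        aux = "not" + _cap(class_name)
        negative.append(Atom(aux, (root,)))
        return {Rule.make([Atom(c.role, (x, z)), Atom(p, (z,))], [], Atom(aux, (x,)))}
    if isinstance(filler, ClassName):
        allowed = [filler.name]
    elif isinstance(filler, Or) and all(isinstance(p, ClassName) for p in filler.parts):
        allowed = [p.name for p in filler.parts]
    else:
        raise LoweringError("ONLY filler must be a name, NOT name, or OR of names")
    aux = "not" + _cap(class_name)
    negative.append(Atom(aux, (root,)))
    viol = Rule.make(
        [Atom(c.role, (x, z))],
        [Atom(p, (z,)) for p in allowed],
        Atom(aux, (x,)),
    )
    return {viol}


def _lower_exactly(
    class_name: str,
    c: Exactly,
    root: Variable,
    base_positive: list[Atom],
    base_negative: list[Atom],
    base_ineqs: list[Inequality],
    aliases: dict[str, str],
) -> set[Rule]:
    """``role EXACTLY n f`` via atLeast_n ∧ not atLeast_{n+1}."""
    if c.n < 1:
        raise LoweringError("EXACTLY requires n >= 1")
    if not isinstance(c.filler, ClassName):
        raise LoweringError("EXACTLY filler must be a class name")
    f = c.filler.name
    alias = aliases.get(f, _cap(f))

    def at_least_rule(k: int) -> tuple[str, Rule]:
        name = f"atLeast{k}{alias}s"
        ys = [Variable(f"Y{i}") for i in range(1, k + 1)]
        pos = list(base_positive)
        for y in ys:
            pos.append(Atom(c.role, (root, y)))
            pos.append(Atom(f, (y,)))
        iq = list(base_ineqs)
        for a in range(k):
            for b in range(a + 1, k):
                iq.append(Inequality(ys[a], ys[b]))
        return name, Rule.make(pos + iq, list(base_negative), Atom(name, (root,)))

    n_name, n_rule = at_least_rule(c.n)
    n1_name, n1_rule = at_least_rule(c.n + 1)
    combine = Rule.make(
        [Atom(n_name, (root,))], [Atom(n1_name, (root,))], Atom(class_name, (root,))
    )
    return {n_rule, n1_rule, combine}
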