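"""Stable-model computation for stratified nonmonotonic existential rules.

The engine materialises the unique stable model of a stratified program by
bottom-up, seminaive fixpoint evaluation, stratum by stratum.  Negation is
evaluated against strictly earlier strata (which are complete by the time a
stratum runs), inequalities hold between syntactically distinct ground terms
(unique name assumption), and existential heads build skolem
:class:`~chemrules.logic.FunctionalTerm` individuals.

Because skolem terms can in principle recur forever, programs are vetted by
:func:`check_termination`: a positive chase from a critical instance (one
fresh constant seeded into every program predicate) that fails as soon as a
created term nests its own function symbol.  A passing program provably
terminates — the number of function symbols bounds the nesting depth.

:func:`enumerate_stable_models_bruteforce` is a deliberately naive
guess-and-check implementation of the general stable-model semantics for
tiny ground programs; it exists as an independent oracle for tests and is
never used by the pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .logic import (
    Atom,
    Constant,
    FunctionalTerm,
    Inequality,
    Program,
    Rule,
    StableModel,
    Term,
    Variable,
    format_atom,
    format_term,
    term_contains_fsym,
    term_depth,
)

__all__ = [
    "Stratification",
    "NotStratifiedError",
    "AcyclicityReport",
    "NonTerminatingProgramError",
    "DepthGuardExceeded",
    "stratify",
    "compute_stable_model",
    "check_termination",
    "enumerate_stable_models_bruteforce",
]

DEFAULT_DEPTH_GUARD = 64


class NotStratifiedError(ValueError):
    """Raised when negation occurs inside a dependency cycle."""

    def __init__(self, cycle: Iterable[str]):
        self.cycle = tuple(sorted(cycle))
        super().__init__(
            "program is not stratified: negative dependency cycle through "
            + ", ".join(self.cycle)
        )


class NonTerminatingProgramError(RuntimeError):
    pass


class DepthGuardExceeded(RuntimeError):
    def __init__(self, term: Term, guard: int):
        self.term = term
        self.guard = guard
        super().__init__(
            f"functional term exceeded nesting depth {guard}: {format_term(term)}"
        )


@dataclass(frozen=True)
class Stratification:
    """Ordered partition of predicates (and rules) into evaluation strata.

    Positive dependencies point to the same or an earlier stratum, negative
    dependencies to a strictly earlier one.
    """

    strata: tuple[frozenset[str], ...]
    levels: dict[str, int]
    rules_by_stratum: tuple[tuple[Rule, ...], ...]


def stratify(program: Program) -> Stratification:
    preds = sorted(program.predicates())
    graph = nx.DiGraph()
    graph.add_nodes_from(preds)
    neg_edges: set[tuple[str, str]] = set()
    for rule in program.rules:
        h = rule.head.predicate
        for a in rule.positive_body:
            graph.add_edge(a.predicate, h)
        for a in rule.negative_body:
            graph.add_edge(a.predicate, h)
            neg_edges.add((a.predicate, h))

    scc_of: dict[str, int] = {}
    sccs = list(nx.strongly_connected_components(graph))
    for i, comp in enumerate(sccs):
        for p in comp:
            scc_of[p] = i
    for (u, v) in neg_edges:
        if scc_of[u] == scc_of[v]:
            raise NotStratifiedError(sccs[scc_of[u]])

    # Level assignment over the condensation DAG.
    cond = nx.condensation(graph, scc=sccs)
    level_of_scc = {n: 0 for n in cond.nodes}
    for n in nx.topological_sort(cond):
        for succ in cond.successors(n):
            members_n = cond.nodes[n]["members"]
            members_s = cond.nodes[succ]["members"]
            negative = any(
                (u, v) in neg_edges for u in members_n for v in members_s
            )
            bump = level_of_scc[n] + (1 if negative else 0)
            if bump > level_of_scc[succ]:
                level_of_scc[succ] = bump

    levels = {p: level_of_scc[scc_of[p]] for p in preds}
    n_strata = max(levels.values(), default=0) + 1
    strata = tuple(
        frozenset(p for p in preds if levels[p] == i) for i in range(n_strata)
    )
    rules_sorted = sorted(program.rules, key=str)
    rules_by_stratum = tuple(
        tuple(r for r in rules_sorted if levels[r.head.predicate] == i)
        for i in range(n_strata)
    )
    return Stratification(strata, levels, rules_by_stratum)


# ---------------------------------------------------------------------------
# Fact storage and joins


class _FactStore:
    """Ground facts indexed by predicate and by (predicate, first argument)."""

    def __init__(self) -> None:
        self.by_pred: dict[str, set[tuple[Term, ...]]] = {}
        self.index0: dict[str, dict[Term, list[tuple[Term, ...]]]] = {}

    def add(self, atom: Atom) -> bool:
        rel = self.by_pred.setdefault(atom.predicate, set())
        if atom.args in rel:
            return False
        rel.add(atom.args)
        if len(atom.args) > 1:
            self.index0.setdefault(atom.predicate, {}).setdefault(
                atom.args[0], []
            ).append(atom.args)
        return True

    def __contains__(self, atom: Atom) -> bool:
        return atom.args in self.by_pred.get(atom.predicate, ())

    def candidates(self, predicate: str, first_arg: Optional[Term]):
        if first_arg is not None and predicate in self.index0:
            return self.index0[predicate].get(first_arg, ())
        return self.by_pred.get(predicate, ())

    def all_atoms(self) -> Iterable[Atom]:
        for pred, rel in self.by_pred.items():
            for args in rel:
                yield Atom(pred, args)


def _walk(term: Term, subst: dict) -> Term:
    if isinstance(term, Variable):
        return subst.get(term, term)
    if isinstance(term, FunctionalTerm):
        return FunctionalTerm(term.fsym, _walk(term.arg, subst))
    return term


def _unify_args(pattern: tuple[Term, ...], ground: tuple[Term, ...], subst: dict):
    """Extend ``subst`` so that pattern == ground, or return None."""
    out = subst
    stack = list(zip(pattern, ground))
    while stack:
        p, g = stack.pop()
        if isinstance(p, Variable):
            bound = out.get(p)
            if bound is None:
                if out is subst:
                    out = dict(subst)
                out[p] = g
            elif bound != g:
                return None
        elif isinstance(p, FunctionalTerm):
            if not isinstance(g, FunctionalTerm) or g.fsym != p.fsym:
                return None
            stack.append((p.arg, g.arg))
        elif p != g:
            return None
    return out


@dataclass
class _RulePlan:
    rule: Rule
    atoms: tuple[Atom, ...]  # canonical order of the positive body


def _plan(rule: Rule) -> _RulePlan:
    return _RulePlan(rule, tuple(sorted(rule.positive_body, key=format_atom)))


class _NestingViolation(Exception):
    def __init__(self, witness: FunctionalTerm):
        self.witness = witness


def _head_fact(
    head: Atom,
    subst: dict,
    depth_guard: int,
    track_nesting: bool,
) -> Atom:
    args = []
    for a in head.args:
        t = _walk(a, subst)
        if isinstance(t, FunctionalTerm):
            if track_nesting and term_contains_fsym(t.arg, t.fsym):
                raise _NestingViolation(t)
            if term_depth(t) > depth_guard:
                raise DepthGuardExceeded(t, depth_guard)
        args.append(t)
    return Atom(head.predicate, tuple(args))


def _evaluate_rule(
    plan: _RulePlan,
    store: _FactStore,
    delta: dict[str, set[tuple[Term, ...]]],
    depth_guard: int,
    track_nesting: bool,
) -> set[Atom]:
    """All head facts derivable with at least one body atom matched in delta."""
    rule = plan.rule
    derived: set[Atom] = set()
    n = len(plan.atoms)
    if n == 0:
        # Ground-head rule with (at most) inequalities in the body.
        if all(iq.holds() for iq in rule.inequalities) and not any(
            a in store for a in rule.negative_body
        ):
            derived.add(_head_fact(rule.head, {}, depth_guard, track_nesting))
        return derived

    head_vars = set(rule.head.variables())
    for d_idx in range(n):
        if plan.atoms[d_idx].predicate not in delta:
            continue
        substs = _join(plan, d_idx, store, delta, head_vars)
        for subst in substs:
            derived.add(_head_fact(rule.head, subst, depth_guard, track_nesting))
    return derived


def _join(
    plan: _RulePlan,
    d_idx: int,
    store: _FactStore,
    delta: dict[str, set[tuple[Term, ...]]],
    head_vars: set[Variable],
) -> list[dict]:
    rule = plan.rule
    pending_atoms = list(range(len(plan.atoms)))
    pending_ineqs = list(rule.inequalities)
    pending_negs = sorted(rule.negative_body, key=format_atom)

    atom_vars = {i: set(plan.atoms[i].variables()) for i in pending_atoms}

    # Seed with the delta atom.
    substs: list[dict] = []
    datom = plan.atoms[d_idx]
    for args in delta[datom.predicate]:
        if args in store.by_pred.get(datom.predicate, ()):
            s = _unify_args(datom.args, args, {})
            if s is not None:
                substs.append(s if s else {})
    pending_atoms.remove(d_idx)
    bound: set[Variable] = set(atom_vars[d_idx])

    def needed_vars() -> set[Variable]:
        need = set(head_vars)
        for i in pending_atoms:
            need |= atom_vars[i]
        for iq in pending_ineqs:
            need.update(iq.variables())
        for a in pending_negs:
            need.update(a.variables())
        return need

    def simplify(substs: list[dict]) -> list[dict]:
        # Check inequalities / negated atoms as soon as they are ground, then
        # project out variables no longer needed (dedup keeps joins small).
        nonlocal pending_ineqs, pending_negs
        ready_ineqs = [iq for iq in pending_ineqs if set(iq.variables()) <= bound]
        ready_negs = [a for a in pending_negs if set(a.variables()) <= bound]
        if ready_ineqs:
            pending_ineqs = [iq for iq in pending_ineqs if iq not in ready_ineqs]
            substs = [
                s for s in substs if all(iq.substitute(s).holds() for iq in ready_ineqs)
            ]
        if ready_negs:
            pending_negs = [a for a in pending_negs if a not in ready_negs]
            substs = [
                s
                for s in substs
                if not any(a.substitute(s) in store for a in ready_negs)
            ]
        keep = bound & needed_vars()
        if keep != bound:
            seen = set()
            projected = []
            for s in substs:
                key = tuple((v, s[v]) for v in sorted(keep, key=lambda v: v.name))
                if key not in seen:
                    seen.add(key)
                    projected.append({v: s[v] for v in keep})
            substs = projected
            bound.clear()
            bound.update(keep)
        return substs

    substs = simplify(substs)
    while pending_atoms and substs:
        # Greedy: most bound variables, then smaller relation, then name.
        def score(i: int):
            a = plan.atoms[i]
            nbound = len(atom_vars[i] & bound)
            size = len(store.by_pred.get(a.predicate, ()))
            return (-nbound, size, format_atom(a))

        nxt = min(pending_atoms, key=score)
        pending_atoms.remove(nxt)
        atom = plan.atoms[nxt]
        out: list[dict] = []
        first = atom.args[0]
        for s in substs:
            key: Optional[Term] = None
            if len(atom.args) > 1:
                fa = _walk(first, s)
                if not isinstance(fa, Variable) and not any(
                    True for _ in _pattern_vars(fa)
                ):
                    key = fa
            for args in store.candidates(atom.predicate, key):
                s2 = _unify_args(atom.args, args, s)
                if s2 is not None:
                    out.append(dict(s2) if s2 is s else s2)
        bound |= atom_vars[nxt]
        substs = simplify(out)
    return substs


def _pattern_vars(term: Term):
    if isinstance(term, Variable):
        yield term
    elif isinstance(term, FunctionalTerm):
        yield from _pattern_vars(term.arg)


# ---------------------------------------------------------------------------
# Stable model computation


def _run_strata(
    rules_by_stratum: Iterable[Iterable[Rule]],
    facts: Iterable[Atom],
    depth_guard: int,
    track_nesting: bool = False,
    max_facts: Optional[int] = None,
) -> _FactStore:
    store = _FactStore()
    for f in sorted(facts, key=format_atom):
        store.add(f)
    for stratum_rules in rules_by_stratum:
        plans = [_plan(r) for r in stratum_rules]
        # Initial delta: everything derived so far.
        delta: dict[str, set[tuple[Term, ...]]] = {}
        for pred, rel in store.by_pred.items():
            delta[pred] = set(rel)
        first_round = True
        while delta or first_round:
            new: set[Atom] = set()
            for plan in plans:
                if first_round and not plan.atoms:
                    new |= _evaluate_rule(plan, store, delta, depth_guard, track_nesting)
                elif plan.atoms:
                    new |= _evaluate_rule(plan, store, delta, depth_guard, track_nesting)
            first_round = False
            delta = {}
            for fact in sorted(new, key=format_atom):
                if store.add(fact):
                    delta.setdefault(fact.predicate, set()).add(fact.args)
            if max_facts is not None:
                total = sum(len(rel) for rel in store.by_pred.values())
                if total > max_facts:
                    raise _ChaseBudgetExceeded(total)
    return store


class _ChaseBudgetExceeded(Exception):
    def __init__(self, n_facts: int):
        self.n_facts = n_facts


def compute_stable_model(
    program: Program,
    *,
    check: bool = True,
    depth_guard: int = DEFAULT_DEPTH_GUARD,
) -> StableModel:
    """Materialise the unique stable model of a stratified program.

    With ``check=True`` (default) the program must first pass
    :func:`check_termination`; with ``check=False`` the caller takes
    responsibility and the ``depth_guard`` backstop raises
    :class:`DepthGuardExceeded` if skolem terms nest too deeply.

    The result is independent of rule and fact iteration order.
    """
    if check:
        report = check_termination(program)
        if not report.passed:
            raise NonTerminatingProgramError(
                "program failed the termination (acyclicity) check; "
                f"witness: {report.witness_text()}"
            )
    strat = stratify(program)
    store = _run_strata(strat.rules_by_stratum, program.facts, depth_guard)
    return StableModel(frozenset(store.all_atoms()))


# ---------------------------------------------------------------------------
# Termination (acyclicity) check


@dataclass(frozen=True)
class AcyclicityReport:
    """Outcome of the conservative chase-based termination test.

    ``passed`` guarantees that stable-model computation terminates from any
    seed facts.  On failure, ``witness`` is a functional term in which one
    function symbol occurs twice along a nesting chain.
    """

    passed: bool
    witness: Optional[FunctionalTerm] = None
    note: str = ""

    def witness_text(self) -> str:
        return format_term(self.witness) if self.witness is not None else self.note


CRITICAL_CONSTANT = Constant("critical_instance")


def check_termination(
    program: Program,
    *,
    depth_guard: int = DEFAULT_DEPTH_GUARD,
    max_facts: int = 2_000_000,
) -> AcyclicityReport:
    """Conservative acyclicity check via a chase from the critical instance.

    Negation and inequalities are dropped (which can only add derivations)
    and every predicate of the program is seeded with a single fresh
    constant; the chase then over-approximates any concrete run.  The check
    fails iff some derived skolem term nests its own function symbol — the
    "special symbol" inspected in the transformed program — otherwise the
    chase reaches a fixpoint and the program is guaranteed to terminate.
    """
    arities: dict[str, int] = {}
    for r in program.rules:
        for a in itertools.chain(r.positive_body, r.negative_body, (r.head,)):
            arities[a.predicate] = a.arity
    for f in program.facts:
        arities[f.predicate] = f.arity
    seed = [
        Atom(pred, (CRITICAL_CONSTANT,) * arity)
        for pred, arity in sorted(arities.items())
    ]
    stripped = sorted(
        {Rule(r.positive_body, frozenset(), r.head, frozenset()) for r in program.rules},
        key=str,
    )
    try:
        _run_strata(
            [stripped], seed, depth_guard, track_nesting=True, max_facts=max_facts
        )
    except _NestingViolation as v:
        return AcyclicityReport(False, witness=v.witness)
    except DepthGuardExceeded as e:
        term = e.term if isinstance(e.term, FunctionalTerm) else None
        return AcyclicityReport(False, witness=term, note=str(e))
    except _ChaseBudgetExceeded as e:
        return AcyclicityReport(
            False, note=f"chase exceeded the fact budget ({e.n_facts} facts)"
        )
    return AcyclicityReport(True)


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)


def enumerate_stable_models_bruteforce(
    program: Program, *, max_base: int = 16
) -> list[StableModel]:
    """All stable models of a tiny ground program by exhaustive guess-and-check.

    For every subset ``M`` of the Herbrand base, builds the
    Gelfond–Lifschitz reduct w.r.t. ``M`` (drop rules whose negated body
    meets ``M``, then erase negation), computes its least model and keeps
    ``M`` iff it equals that least model.  Refuses bases larger than
    ``max_base`` — this is a test oracle, not an engine.
    """
    base: set[Atom] = set(program.facts)
    for r in program.rules:
        for a in itertools.chain(r.positive_body, r.negative_body, (r.head,)):
            if not a.is_ground():
                raise ValueError(f"brute-force oracle requires a ground program: {a}")
            base.add(a)
    base_sorted = sorted(base, key=format_atom)
    if len(base_sorted) > max_base:
        raise ValueError(
            f"Herbrand base has {len(base_sorted)} atoms, oracle bound is {max_base}"
        )

    rules = [r for r in program.rules if all(iq.holds() for iq in r.inequalities)]
    models: list[StableModel] = []
    for bits in itertools.product((False, True), repeat=len(base_sorted)):
        candidate = frozenset(a for a, b in zip(base_sorted, bits) if b)
        reduct = [
            (r.positive_body, r.head)
            for r in rules
            if not (r.negative_body & candidate)
        ]
        least = set(program.facts)
        changed = True
        while changed:
            changed = False
            for body, head in reduct:
                if head not in least and body <= least:
                    least.add(head)
                    changed = True
        if frozenset(least) == candidate:
            models.append(StableModel(candidate))
    return models
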