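"""Terms, rules, safety checking and the textual rule dialect."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemrules.logic import (
    Atom,
    Constant,
    DialectSyntaxError,
    FunctionSymbol,
    FunctionalTerm,
    Inequality,
    Program,
    Rule,
    UnsafeRuleError,
    Variable,
    check_safety,
    format_rules,
    make_rules,
    parse_rules,
)

X, Y = Variable("X"), Variable("Y")
a = Constant("a")


class TestSafety:
    def test_negation_guarded_by_positive_atom_is_safe(self):
        rule = Rule.make(
            [Atom("molecule", (X,))], [Atom("unsaturated", (X,))], Atom("saturated", (X,))
        )
        assert check_safety(rule).ok

    def test_purely_negative_rule_is_unsafe(self):
        rule = Rule.make([], [Atom("p", (X,))], Atom("q", (X,)))
        report = check_safety(rule)
        assert not report.ok and report.unsafe_variables == {X}

    def test_inequality_variable_needs_positive_occurrence(self):
        rule = Rule.make([Atom("p", (X,)), Inequality(X, Y)], [], Atom("q", (X,)))
        report = check_safety(rule)
        # Oracle: set difference of variable occurrences.
        assert not report.ok and report.unsafe_variables == {Y}

    def test_functional_terms_forbidden_under_negation(self):
        f = FunctionalTerm(FunctionSymbol("m", 1), X)
        rule = Rule.make([Atom("p", (X,))], [Atom("q", (f,))], Atom("r", (X,)))
        assert not check_safety(rule).ok

    def test_program_rejects_unsafe_rules_and_nonground_facts(self):
        with pytest.raises(UnsafeRuleError):
            Program.make([Rule.make([], [Atom("p", (X,))], Atom("q", (X,)))])
        with pytest.raises(ValueError, match="ground"):
            Program.make([], [Atom("p", (X,))])


class TestTerms:
    def test_functional_term_equality_is_syntactic(self):
        f1 = FunctionalTerm(FunctionSymbol("mol", 1), a)
        f1b = FunctionalTerm(FunctionSymbol("mol", 1), a)
        f2 = FunctionalTerm(FunctionSymbol("mol", 2), a)
        other = FunctionalTerm(FunctionSymbol("othermol", 1), a)
        assert f1 == f1b
        assert f1 != f2 and f1 != other
        assert Inequality(f1, f2).holds() and not Inequality(f1, f1b).holds()

    def test_multi_conjunct_head_normalisation(self):
        body = [Atom("p", (X,))]
        heads = [Atom("q", (X,)), Atom("r", (X,)), Atom("s", (X,))]
        rules = make_rules(body, [], heads)
        assert len(rules) == 3
        assert {r.head.predicate for r in rules} == {"q", "r", "s"}
        assert all(r.positive_body == frozenset(body) for r in rules)


class TestDialect:
    def test_parse_background_style_rules(self):
        prog = parse_rules(
            """
            % bond inclusions
            bond(X, Y) :- single(X, Y).
            bond(X, Y) :- double(X, Y).
            triple(X, Y) -> bond(X, Y).
            """
        )
        assert len(prog.rules) == 3
        assert all(not r.negative_body for r in prog.rules)

    def test_empty_text(self):
        prog = parse_rules("")
        assert not prog.rules and not prog.facts

    def test_functional_terms_and_negation(self):
        text = "o(f1@asc(a)).\nq(X) :- p(X), X != b, not r(X).\n"
        prog = parse_rules(text)
        (fact,) = prog.facts
        assert fact.args[0] == FunctionalTerm(FunctionSymbol("asc", 1), a)
        (rule,) = prog.rules
        assert rule.negative_body and rule.inequalities

    def test_syntax_error_is_positioned(self):
        with pytest.raises(DialectSyntaxError) as err:
            parse_rules("p(a).\nq(X) :- \n")
        assert err.value.line >= 2

    def test_format_is_sorted_and_deterministic(self):
        text = "q(X) :- b(X), a(X), not z(X).\np(a).\n"
        out = format_rules(parse_rules(text))
        assert out == format_rules(parse_rules(out))
        assert out.index("a(X)") < out.index("b(X)") < out.index("not z(X)")


# Round-trip property on randomly generated programs.

_pred = st.sampled_from(["p", "q", "r", "edge", "hasAtom"])
_var = st.sampled_from([X, Y, Variable("Z")])
_const = st.sampled_from([a, Constant("b"), Constant("c")])
_term = st.one_of(
    _var,
    _const,
    st.builds(
        FunctionalTerm,
        st.builds(FunctionSymbol, st.sampled_from(["m1", "m2"]), st.integers(1, 3)),
        _var,
    ),
)
_atom = st.builds(
    Atom, _pred, st.lists(_var | _const, min_size=1, max_size=2).map(tuple)
)


@st.composite
def _rules(draw):
    pos = draw(st.lists(_atom, min_size=1, max_size=3))
    body_vars = {v for atm in pos for v in atm.variables()}
    head_args = draw(
        st.lists(
            st.sampled_from(sorted(body_vars, key=str) + [a]), min_size=1, max_size=2
        )
    )
    neg = draw(st.lists(_atom, min_size=0, max_size=2))
    neg = [n for n in neg if set(n.variables()) <= body_vars]
    return Rule.make(pos, neg, Atom(draw(_pred), tuple(head_args)))


@given(st.lists(_rules(), min_size=0, max_size=6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_dialect_round_trip(rules):
    prog = Program.make(rules)
    text = format_rules(prog)
    assert parse_rules(text).rules == prog.rules
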