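"""Stratification, stable-model computation, oracle equivalence, termination."""

import random

import pytest

from chemrules.classes import builtin_class_rules
from chemrules.engine import (
    DepthGuardExceeded,
    NotStratifiedError,
    check_termination,
    compute_stable_model,
    enumerate_stable_models_bruteforce,
    stratify,
)
from chemrules.logic import (
    Atom,
    Constant,
    FunctionSymbol,
    FunctionalTerm,
    Program,
    Rule,
    Variable,
    parse_rules,
)
from chemrules.reference import ascorbic_acid_dg
from chemrules.translation import dg_to_structure_rules, molecule_seed_fact

X = Variable("X")
a = Constant("a")


def molecule_kb(classes="all"):
    rules = dg_to_structure_rules(ascorbic_acid_dg()) | builtin_class_rules(classes)
    return Program.make(rules, [molecule_seed_fact("ascorbicAcid", "a")])


def random_ground_program(rng: random.Random) -> Program:
    """A random ground program that is stratified by construction."""
    preds = [f"p{i}" for i in range(rng.randint(3, 6))]
    level = {p: rng.randint(0, 2) for p in preds}
    rules = []
    for _ in range(rng.randint(2, 8)):
        head = rng.choice(preds)
        pos = [
            Atom(p, (a,))
            for p in rng.sample(preds, rng.randint(0, 2))
            if level[p] <= level[head]
        ]
        neg = [
            Atom(p, (a,))
            for p in rng.sample(preds, rng.randint(0, 2))
            if level[p] < level[head]
        ]
        rules.append(Rule.make(pos, neg, Atom(head, (a,))))
    facts = [Atom(p, (a,)) for p in preds if rng.random() < 0.3]
    return Program.make(rules, facts)


class TestStratify:
    def test_program_without_negation_is_single_stratum(self):
        strat = stratify(parse_rules("q(X) :- p(X).\nr(X) :- q(X).\np(a).\n"))
        assert len(strat.strata) == 1

    def test_negation_pushes_head_to_higher_stratum(self):
        strat = stratify(parse_rules("q(X) :- p(X).\nr(X) :- q(X), not p(X).\np(a).\n"))
        assert strat.levels["p"] < strat.levels["r"]
        assert strat.levels["q"] < strat.levels["r"]

    def test_molecule_kb_stratification_order(self):
        strat = stratify(molecule_kb())
        lv = strat.levels
        # structure < derived helpers < classes built on their negation
        assert lv["c"] < lv["notHydroCarbon"] < lv["hydroCarbon"]
        assert lv["unsaturated"] < lv["saturated"]
        assert lv["carbonEntity"] < lv["inorganic"]
        assert lv["atLeast3Carbons"] < lv["exactly2Carbons"]
        assert lv["cyclic"] < lv["alkane"]
        assert lv["middleOxygen"] < lv["carboxylicAcid"]

    def test_negative_cycle_reported(self):
        with pytest.raises(NotStratifiedError) as err:
            stratify(parse_rules("q(X) :- p(X), not q(X).\np(a).\n"))
        assert "q" in err.value.cycle


class TestStableModel:
    def test_facts_only(self):
        prog = Program.make([], [Atom("p", (a,))])
        assert compute_stable_model(prog).facts == frozenset({Atom("p", (a,))})

    def test_result_independent_of_rule_iteration_order(self):
        rng = random.Random(7)
        prog = random_ground_program(rng)
        rules = sorted(prog.rules, key=str)
        shuffled = list(rules)
        rng.shuffle(shuffled)
        m1 = compute_stable_model(Program.make(rules, prog.facts), check=False)
        m2 = compute_stable_model(Program.make(shuffled, prog.facts), check=False)
        assert m1.facts == m2.facts

    def test_matches_bruteforce_oracle_on_random_programs(self):
        rng = random.Random(202)
        for _ in range(50):
            prog = random_ground_program(rng)
            models = enumerate_stable_models_bruteforce(prog)
            assert len(models) == 1  # stratified ⇒ unique stable model
            assert compute_stable_model(prog, check=False).facts == models[0].facts

    def test_skolem_terms_have_depth_one_and_hasatom_count_matches(self):
        model = compute_stable_model(molecule_kb(), check=False)
        has_atom = model.with_predicate("hasAtom")
        assert len(has_atom) == 13
        for fact in model.facts:
            for term in fact.args:
                depth = 0
                while isinstance(term, FunctionalTerm):
                    depth += 1
                    term = term.arg
                assert depth <= 1


class TestBruteforce:
    def test_single_model_with_default_negation(self):
        prog = parse_rules("p(a).\nq(a) :- not r(a).\n")
        models = enumerate_stable_models_bruteforce(prog)
        assert [sorted(map(str, m.facts)) for m in models] == [["p(a)", "q(a)"]]

    def test_classic_no_stable_model(self):
        prog = Program.make([Rule.make([], [Atom("p", (a,))], Atom("p", (a,)))])
        assert enumerate_stable_models_bruteforce(prog) == []

    def test_even_loop_has_two_models(self):
        prog = parse_rules("p(a) :- not q(a).\nq(a) :- not p(a).\n")
        models = enumerate_stable_models_bruteforce(prog)
        assert sorted(sorted(map(str, m.facts)) for m in models) == [["p(a)"], ["q(a)"]]

    def test_refuses_large_base(self):
        facts = [Atom(f"p{i}", (a,)) for i in range(20)]
        with pytest.raises(ValueError, match="bound"):
            enumerate_stable_models_bruteforce(Program.make([], facts), max_base=16)


class TestTermination:
    def test_molecule_kbs_pass(self):
        assert check_termination(molecule_kb()).passed
        assert check_termination(molecule_kb("no-cyclic")).passed

    def test_function_free_program_passes(self):
        assert check_termination(parse_rules("q(X) :- p(X).\np(a).\n")).passed

    def test_term_generating_loop_fails_with_witness(self):
        f = FunctionSymbol("g", 1)
        loop = Program.make(
            [
                Rule.make(
                    [Atom("a", (X,))],
                    [],
                    Atom("r", (X, FunctionalTerm(f, X))),
                ),
                Rule.make([Atom("r", (X, Variable("Y")))], [], Atom("a", (Variable("Y"),))),
            ],
            [Atom("a", (a,))],
        )
        report = check_termination(loop)
        assert not report.passed
        witness = report.witness
        assert witness is not None and witness.fsym == f
        assert isinstance(witness.arg, FunctionalTerm) and witness.arg.fsym == f

    def test_compute_refuses_nonterminating_program(self):
        f = FunctionSymbol("g", 1)
        loop = Program.make(
            [
                Rule.make([Atom("a", (X,))], [], Atom("a", (FunctionalTerm(f, X),))),
            ],
            [Atom("a", (a,))],
        )
        from chemrules.engine import NonTerminatingProgramError

        with pytest.raises(NonTerminatingProgramError):
            compute_stable_model(loop)
        with pytest.raises(DepthGuardExceeded):
            compute_stable_model(loop, check=False, depth_guard=8)

    def test_passing_programs_never_trip_depth_guard(self):
        """Soundness fuzz: a passing check implies bounded skolem nesting."""
        rng = random.Random(99)
        passed = 0
        for _ in range(100):
            prog = random_ground_program(rng)
            # Sprinkle in an existential rule now and then.
            rules = set(prog.rules)
            if rng.random() < 0.5:
                f = FunctionSymbol(f"m{rng.randint(1, 3)}", rng.randint(1, 2))
                src = f"p{rng.randint(0, 2)}"
                dst = f"p{rng.randint(0, 2)}"
                rules.add(
                    Rule.make([Atom(src, (X,))], [], Atom(dst, (FunctionalTerm(f, X),)))
                )
            try:
                prog = Program.make(rules, prog.facts)
            except ValueError:
                continue
            report = check_termination(prog)
            if report.passed:
                try:
                    stratify(prog)
                except NotStratifiedError:
                    continue  # engine scope is the stratified fragment
                passed += 1
                compute_stable_model(prog, check=False, depth_guard=16)
        assert passed >= 30  # the fuzz actually exercised passing programs
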