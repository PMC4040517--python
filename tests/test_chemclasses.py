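"""The built-in class registry and the semantic behaviour of its rules."""

import pytest

from chemrules.classes import (
    UnknownClassError,
    builtin_class_rules,
    cyclicity_rules,
    internal_predicates,
    load_extra_classes,
    registry,
    registry_manifest,
    reported_class_predicates,
)
from chemrules.fixtures import FixtureSpec, generate_fixtures
from chemrules.logic import parse_rules
from chemrules.pipeline import classify_molecules
from chemrules.translation import background_rules

from conftest import rules_equivalent


class TestRegistry:
    def test_required_builtins_present(self):
        required = {
            "carbonEntity", "polyatomicEntity", "heteroOrganicEntity",
            "middleOxygen", "carboxylicAcid", "carboxylicEster",
            "atLeast2Carbons", "atLeast3Carbons", "exactly2Carbons",
            "inorganic", "hydroCarbon", "notHydroCarbon",
            "unsaturated", "saturated", "cyclic", "alkane",
        }
        assert required <= set(registry())

    def test_inorganic_rule_as_reference(self):
        rules = registry()["inorganic"].rules
        expected = parse_rules("inorganic(X) :- molecule(X), not carbonEntity(X).").rules
        assert rules_equivalent(rules, expected)

    def test_alkane_rule_as_reference(self):
        expected = parse_rules(
            "alkane(X) :- saturated(X), hydroCarbon(X), not cyclic(X)."
        ).rules
        assert rules_equivalent(registry()["alkane"].rules, expected)

    def test_empty_selection_returns_background_only(self):
        assert builtin_class_rules([]) == background_rules()

    def test_selection_closes_over_prerequisites(self):
        rules = builtin_class_rules(["alkane"])
        heads = {r.head.predicate for r in rules}
        assert {"alkane", "saturated", "hydroCarbon", "cyclic", "unsaturated"} <= heads

    def test_no_cyclic_mode_drops_cyclicity_group(self):
        heads = {r.head.predicate for r in builtin_class_rules("no-cyclic")}
        assert "cyclic" not in heads and "alkane" not in heads
        heads2 = {r.head.predicate for r in builtin_class_rules("all", with_cyclic=False)}
        assert "cyclic" not in heads2

    def test_unknown_class_rejected(self):
        with pytest.raises(UnknownClassError):
            builtin_class_rules(["benzeneRing"])

    def test_class_predicates_never_head_structure_vocabulary(self):
        structural = {"hasAtom", "single", "double", "triple", "o", "c", "h",
                      "positive", "negative", "molecule"}
        for d in registry().values():
            for r in d.rules:
                assert r.head.predicate not in structural

    def test_manifest_and_internal_predicates(self):
        rows = registry_manifest()
        assert all(r["provenance"] == "core" for r in rows)
        assert {r["group"] for r in rows} == {
            "existence", "cardinality", "exclusive", "cyclicity"
        }
        assert "reach" in internal_predicates()
        assert "middleOxygen" not in reported_class_predicates()
        assert "cyclic" in reported_class_predicates()

    def test_extra_classes_load_but_stay_out_of_core(self):
        extra = load_extra_classes()
        assert extra  # lowers without error
        assert "ketone" not in registry()
        assert {r.head.predicate for r in extra} >= {"ketone", "amine", "halogenAtom"}


class TestCyclicity:
    def test_rule_count_is_stable(self):
        # one first-step rule, four guarded recursive steps, one closing rule
        assert len(cyclicity_rules()) == 6

    def test_benzene_is_cyclic_ethane_is_not(self, benzene_mol, ethane_mol):
        result = classify_molecules([benzene_mol, ethane_mol], ["cyclic"])
        assert "cyclic" in result.assignments["benzene"]
        assert "cyclic" not in result.assignments["ethane"]

    def test_reference_molecule_is_cyclic(self):
        from chemrules.reference import ascorbic_acid_molfile

        result = classify_molecules([ascorbic_acid_molfile()], ["cyclic"])
        assert "cyclic" in result.assignments["ascorbic_acid"]


@pytest.fixture(scope="module")
def batch():
    mols = generate_fixtures(FixtureSpec(seed=23, n_molecules=60))
    result = classify_molecules([m.molfile for m in mols])
    return mols, result.assignments


class TestClassSemantics:

    def test_saturation_dichotomy(self, batch):
        """Exactly one of saturated/unsaturated holds per molecule."""
        _, assignments = batch
        for classes in assignments.values():
            assert ("saturated" in classes) != ("unsaturated" in classes)

    def test_hydrocarbon_and_inorganic_exclusive(self, batch):
        _, assignments = batch
        for classes in assignments.values():
            assert not ({"hydroCarbon", "inorganic"} <= set(classes))

    def test_exactly_two_carbons_matches_count_oracle(self, batch):
        mols, assignments = batch
        for m in mols:
            assert ("exactly2Carbons" in assignments[m.name]) == (m.n_carbons == 2)

    def test_alkane_implication(self, batch):
        _, assignments = batch
        for classes in assignments.values():
            if "alkane" in classes:
                assert "saturated" in classes
                assert "hydroCarbon" in classes
                assert "cyclic" not in classes

    def test_acid_and_ester_recognition_on_hand_fixtures(
        self, acetic_acid_mol, oxalic_acid_mol, methyl_acetate_mol, acetate_anion_mol
    ):
        """Acids are exactly {acetic, oxalic}; esters exactly {methyl acetate}.

        The charged-oxygen and middle-oxygen guards must keep the acetate
        anion and the ester bridge oxygen from matching the carboxy pattern.
        """
        result = classify_molecules(
            [acetic_acid_mol, oxalic_acid_mol, methyl_acetate_mol, acetate_anion_mol],
            ["carboxylicAcid", "carboxylicEster"],
        )
        acids = {m for m, cls in result.assignments.items() if "carboxylicAcid" in cls}
        esters = {m for m, cls in result.assignments.items() if "carboxylicEster" in cls}
        assert acids == {"acetic_acid", "oxalic_acid"}
        assert esters == {"methyl_acetate"}
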