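"""Molfile parsing, hydrogen suppression and description-graph building."""

import pytest

from chemrules.chem_io import (
    HydrogenSuppressionWarning,
    MolfileParseError,
    UnsupportedElementError,
    build_description_graph,
    parse_molfile,
    parse_sdf,
    suppress_hydrogens,
)
from chemrules.fixtures import FixtureSpec, generate_fixtures
from chemrules.reference import ascorbic_acid_graph

from conftest import molfile


class TestParseMolfile:
    def test_reference_structure(self):
        g = ascorbic_acid_graph()
        assert g.n_atoms == 13
        elements = [a.element for a in g.atoms]
        assert elements.count("O") == 6
        assert elements.count("C") == 6
        assert elements.count("H") == 1
        assert len(g.bonds) == 13
        assert sum(1 for b in g.bonds if b.order == 2) == 2
        assert sum(1 for b in g.bonds if b.stereo_flag != 0) == 1

    def test_empty_molfile(self):
        g = parse_molfile(molfile("empty", [], []))
        assert g.n_atoms == 0 and not g.bonds

    def test_ethanol_against_independent_parser(self, ethanol_mol):
        """Cross-check the hand-written parser against rdkit on a fixture."""
        from rdkit import Chem

        ours = parse_molfile(ethanol_mol)
        ref = Chem.MolFromMolBlock(ethanol_mol, removeHs=False)
        assert ref is not None
        assert [a.element for a in ours.atoms] == [
            atom.GetSymbol() for atom in ref.GetAtoms()
        ]
        ref_bonds = {
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) + 1,
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) + 1,
                int(b.GetBondTypeAsDouble()),
            )
            for b in ref.GetBonds()
        }
        ours_bonds = {(*b.pair(), b.order) for b in ours.bonds}
        assert ours_bonds == ref_bonds

    def test_chg_property_overrides_atom_block(self):
        # Atom-block code 3 (= +1) on atom 1 is reset by the M CHG line,
        # which charges atom 2 instead.
        text = molfile("chg", ["N", "O"], [(1, 2, 1)], charges=[(2, -1)])
        lines = text.splitlines()
        lines[4] = lines[4][:36] + "  3" + lines[4][39:]
        g = parse_molfile("\n".join(lines) + "\n")
        assert [a.formal_charge for a in g.atoms] == [0, -1]

    def test_atom_block_charge_codes_without_chg(self):
        text = molfile("codes", ["N", "O"], [(1, 2, 1)])
        lines = text.splitlines()
        lines[4] = lines[4][:36] + "  3" + lines[4][39:]  # code 3 = +1
        lines[5] = lines[5][:36] + "  5" + lines[5][39:]  # code 5 = -1
        g = parse_molfile("\n".join(lines) + "\n")
        assert [a.formal_charge for a in g.atoms] == [1, -1]

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda t: t.replace("1  2  1", "1  2  4", 1), "bond order"),
            (lambda t: t.replace("V2000", "V3000"), "V3000"),
            (lambda t: t.replace("  1  2  1", "  1  9  1", 1), "dangling"),
            (lambda t: t.replace("  2  1", "abc  1", 1), "malformed"),
        ],
    )
    def test_structured_errors(self, ethane_mol, mutate, message):
        with pytest.raises(MolfileParseError) as err:
            parse_molfile(mutate(ethane_mol))
        assert message.lower() in str(err.value).lower()
        assert "line" in str(err.value)

    def test_parallel_bond_rejected(self):
        text = molfile("par", ["C", "C"], [(1, 2, 1), (2, 1, 2)])
        with pytest.raises(MolfileParseError, match="parallel"):
            parse_molfile(text)

    def test_sdf_multirecord(self, water_mol, ethane_mol):
        graphs = parse_sdf(water_mol + "$$$$\n" + ethane_mol + "$$$$\n")
        assert [g.name for g in graphs] == ["water", "ethane"]


class TestSuppressHydrogens:
    def test_water_collapses_to_single_oxygen(self, water_mol):
        g = suppress_hydrogens(parse_molfile(water_mol))
        assert [a.element for a in g.atoms] == ["O"] and not g.bonds

    def test_stereo_hydrogen_is_kept(self):
        g = suppress_hydrogens(ascorbic_acid_graph())
        assert g.n_atoms == 13  # node 13's bond carries a stereo flag
        elements = [a.element for a in g.atoms]
        assert elements.count("O") == 6 and elements.count("C") == 6
        assert elements.count("H") == 1

    def test_no_hydrogens_is_identity(self, ethane_mol):
        g = parse_molfile(ethane_mol)
        assert suppress_hydrogens(g) is g

    def test_idempotent_and_counts_match_oracle(self):
        mols = generate_fixtures(FixtureSpec(seed=11, n_molecules=40))
        for m in mols:
            g = parse_molfile(m.molfile)
            # Oracle: count degree-1 stereo-free hydrogen records directly.
            deg = {a.index: g.degree(a.index) for a in g.atoms}
            plain_h = sum(
                1
                for a in g.atoms
                if a.element == "H"
                and deg[a.index] == 1
                and next(
                    b for b in g.bonds if a.index in (b.from_idx, b.to_idx)
                ).stereo_flag
                == 0
            )
            s = suppress_hydrogens(g)
            assert s.n_atoms == g.n_atoms - plain_h
            assert suppress_hydrogens(s).atoms == s.atoms
            assert [a.index for a in s.atoms] == list(range(1, s.n_atoms + 1))

    def test_bridging_hydrogen_kept_with_warning(self):
        text = molfile("bridge", ["C", "H", "C"], [(1, 2, 1), (2, 3, 1)])
        with pytest.warns(HydrogenSuppressionWarning):
            g = suppress_hydrogens(parse_molfile(text))
        assert [a.element for a in g.atoms] == ["C", "H", "C"]


class TestDescriptionGraph:
    def test_reference_dg(self):
        from chemrules.reference import ascorbic_acid_dg

        dg = ascorbic_acid_dg()
        assert {i: dg.element_label(i) for i in range(1, 14)} == {
            **{i: "o" for i in range(1, 7)},
            **{i: "c" for i in range(7, 13)},
            13: "h",
        }
        assert len(dg.bond_edges) == 13
        doubles = {(i, j) for i, j, lab in dg.bond_edges if lab == "double"}
        assert doubles == {(2, 7), (8, 9)}

    def test_single_neutral_oxygen(self):
        g = parse_molfile(molfile("oxygen", ["O"], []))
        dg = build_description_graph(g, "oxygen")
        assert dg.atom_nodes == {1: frozenset({"o"})} and not dg.bond_edges

    def test_charged_atom_gets_sign_label(self, acetate_anion_mol):
        g = suppress_hydrogens(parse_molfile(acetate_anion_mol))
        dg = build_description_graph(g, "acetate")
        charged = [i for i, labels in dg.atom_nodes.items() if "negative" in labels]
        assert len(charged) == 1
        assert dg.element_label(charged[0]) == "o"

    def test_unknown_element_rejected(self):
        g = parse_molfile(molfile("odd", ["Xx"], []))
        with pytest.raises(UnsupportedElementError, match="Xx"):
            build_description_graph(g, "odd")

    def test_round_trip_preserves_atom_and_bond_multisets(self):
        from collections import Counter

        for m in generate_fixtures(FixtureSpec(seed=5, n_molecules=25)):
            g = suppress_hydrogens(parse_molfile(m.molfile))
            dg = build_description_graph(g, "m")
            assert Counter(a.element.lower() for a in g.atoms) == Counter(
                dg.element_label(i) for i in dg.atom_nodes
            )
            assert Counter(
                (*b.pair(), {1: "single", 2: "double", 3: "triple"}[b.order])
                for b in g.bonds
            ) == Counter(dg.bond_edges)
            n = dg.n_atoms
            assert len(dg.bond_edges) <= n * (n - 1) / 2
            assert all(lab in ("single", "double", "triple") for *_, lab in dg.bond_edges)
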