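"""Shared fixtures: small hand-written molecules and rule-comparison helpers."""

from __future__ import annotations

import itertools

import pytest

from chemrules.logic import Inequality, Rule, Variable, format_rule


def _oriented(iq: Inequality) -> Inequality:
    # Inequality is symmetric; fix an orientation so renamings compare.
    left, right = sorted((iq.left, iq.right), key=str)
    return Inequality(left, right)


def molfile(name, atoms, bonds, charges=()):
    """Build a V2000 molfile text.

    ``atoms`` is a list of element symbols (1-based indices), ``bonds`` a
    list of (i, j, order) or (i, j, order, stereo) tuples, ``charges`` a
    list of (atom_index, charge) pairs emitted as an ``M  CHG`` line.
    """
    lines = [
        name,
        "  test fixture",
        "",
        f"{len(atoms):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for e in atoms:
        lines.append(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {e:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for bond in bonds:
        i, j, order = bond[:3]
        stereo = bond[3] if len(bond) > 3 else 0
        lines.append(f"{i:>3}{j:>3}{order:>3}{stereo:>3}  0  0  0")
    for idx, val in charges:
        lines.append(f"M  CHG  1 {idx:>3} {val:>3}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def water_mol():
    return molfile("water", ["O", "H", "H"], [(1, 2, 1), (1, 3, 1)])


@pytest.fixture
def methane_mol():
    return molfile("methane", ["C", "H", "H", "H", "H"], [(1, k, 1) for k in range(2, 6)])


@pytest.fixture
def ethane_mol():
    return molfile("ethane", ["C", "C"], [(1, 2, 1)])


@pytest.fixture
def ethanol_mol():
    # CH3-CH2-OH with all hydrogens explicit.
    atoms = ["C", "C", "O"] + ["H"] * 6
    bonds = [(1, 2, 1), (2, 3, 1)]
    bonds += [(1, 4, 1), (1, 5, 1), (1, 6, 1), (2, 7, 1), (2, 8, 1), (3, 9, 1)]
    return molfile("ethanol", atoms, bonds)


@pytest.fixture
def benzene_mol():
    # Kekulized benzene ring.
    bonds = [(1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 6, 1), (6, 1, 2)]
    return molfile("benzene", ["C"] * 6, bonds)


@pytest.fixture
def acetic_acid_mol():
    # CH3-C(=O)-OH (hydrogens implicit).
    return molfile("acetic acid", ["C", "C", "O", "O"], [(1, 2, 1), (2, 3, 2), (2, 4, 1)])


@pytest.fixture
def oxalic_acid_mol():
    # HOOC-COOH.
    return molfile(
        "oxalic acid",
        ["C", "C", "O", "O", "O", "O"],
        [(1, 2, 1), (1, 3, 2), (1, 4, 1), (2, 5, 2), (2, 6, 1)],
    )


@pytest.fixture
def methyl_acetate_mol():
    # CH3-C(=O)-O-CH3.
    return molfile(
        "methyl acetate",
        ["C", "C", "O", "O", "C"],
        [(1, 2, 1), (2, 3, 2), (2, 4, 1), (4, 5, 1)],
    )


@pytest.fixture
def acetate_anion_mol():
    # CH3-COO(-): the deprotonated oxygen carries a -1 charge.
    return molfile(
        "acetate",
        ["C", "C", "O", "O"],
        [(1, 2, 1), (2, 3, 2), (2, 4, 1)],
        charges=[(4, -1)],
    )


# ---------------------------------------------------------------------------
# Rule-set comparison up to variable renaming


def rule_canonical(rule: Rule) -> str:
    """Canonical rendering: the minimum over all variable renamings."""
    vs = sorted(
        {
            v
            for part in itertools.chain(
                rule.positive_body, rule.negative_body, [rule.head]
            )
            for v in part.variables()
        }
        | {v for iq in rule.inequalities for v in iq.variables()},
        key=lambda v: v.name,
    )
    best = None
    for perm in itertools.permutations(range(len(vs))):
        mapping = {v: Variable(f"V{j}") for v, j in zip(vs, perm)}
        renamed = Rule.make(
            [a.substitute(mapping) for a in rule.positive_body]
            + [_oriented(iq.substitute(mapping)) for iq in rule.inequalities],
            [a.substitute(mapping) for a in rule.negative_body],
            rule.head.substitute(mapping),
        )
        text = format_rule(renamed)
        if best is None or text < best:
            best = text
    return best


def rules_equivalent(got, expected) -> bool:
    """Set equality of rules up to variable renaming and body-atom order."""
    return sorted(map(rule_canonical, got)) == sorted(map(rule_canonical, expected))
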