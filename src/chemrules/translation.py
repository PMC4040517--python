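"""Description graphs → structure rules, plus the background chemistry rules.

A molecule's description graph is unfolded into existential rules: when the
molecule predicate is instantiated, fresh skolem terms ``f_i(x)`` are
created for its atom nodes, typed with their element (and charge) labels,
and related by their bond-order labels.  Bond-order atoms are emitted in
both directions so that pattern recognition never depends on the arbitrary
atom ordering of the input molfile; ``hasAtom`` stays directed
(molecule → atom).

The background rules encode general chemical knowledge: single/double/triple
bonds are bonds, positive/negative atoms are charged, hydrogens and carbons
are ``horc`` atoms.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .chem_io import DescriptionGraph
from .logic import (
    Atom,
    Constant,
    FunctionSymbol,
    FunctionalTerm,
    Rule,
    Variable,
    make_rules,
)

__all__ = [
    "dg_to_structure_rules",
    "background_rules",
    "molecule_seed_fact",
    "ConstantCollisionError",
]

_X = Variable("X")
_Y = Variable("Y")


def dg_to_structure_rules(dg: DescriptionGraph) -> set[Rule]:
    """Unfold a description graph into one structure rule per head conjunct.

    The (conceptual) single rule is
    ``mol(x) -> molecule(x) ∧ hasAtom(x, f_i(x)) ∧ label(f_i(x)) ∧ ...``;
    it is normalised into one rule per conjunct.  Skolem symbols are
    ``(molecule_predicate, node_index)`` so distinct molecules never share
    functional terms.
    """
    body = [Atom(dg.molecule_predicate, (_X,))]
    skolem = {
        i: FunctionalTerm(FunctionSymbol(dg.molecule_predicate, i), _X)
        for i in dg.atom_nodes
    }
    heads: list[Atom] = [Atom("molecule", (_X,))]
    for i in sorted(dg.atom_nodes):
        heads.append(Atom("hasAtom", (_X, skolem[i])))
        for label in sorted(dg.atom_nodes[i]):
            heads.append(Atom(label, (skolem[i],)))
    for (i, j, label) in sorted(dg.bond_edges):
        heads.append(Atom(label, (skolem[i], skolem[j])))
        heads.append(Atom(label, (skolem[j], skolem[i])))
    return set(make_rules(body, [], heads))


def background_rules() -> set[Rule]:
    """The seven background implications of general chemical knowledge."""
    rules = []
    for order in ("single", "double", "triple"):
        rules.append(Rule.make([Atom(order, (_X, _Y))], [], Atom("bond", (_X, _Y))))
    for sign in ("negative", "positive"):
        rules.append(Rule.make([Atom(sign, (_X,))], [], Atom("charged", (_X,))))
    for elem in ("h", "c"):
        rules.append(Rule.make([Atom(elem, (_X,))], [], Atom("horc", (_X,))))
    return set(rules)


class ConstantCollisionError(ValueError):
    pass


def molecule_seed_fact(
    molecule_predicate: str,
    constant: str,
    existing: Optional[Iterable[str]] = None,
) -> Atom:
    """The seed fact ``mol(c)`` that triggers a molecule's structure rules.

    ``existing`` optionally lists constants already used in the program;
    a collision raises :class:`ConstantCollisionError` since each molecule
    must be instantiated with a fresh constant.
    """
    if existing is not None and constant in set(existing):
        raise ConstantCollisionError(f"constant {constant!r} is already in use")
    return Atom(molecule_predicate, (Constant(constant),))
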