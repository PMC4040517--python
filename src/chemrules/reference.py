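"""Packaged reference structure: ascorbic acid (vitamin C).

The molfile is reconstructed from the molecule's description graph — atom
nodes 1–6 oxygen, 7–12 carbon and one explicit hydrogen (node 13) retained
because its bond carries a stereo annotation; 11 single and 2 double bonds.
It serves as the worked example throughout the documentation and tests:
ascorbic acid is an unsaturated, polyatomic, heteroorganic, cyclic entity
containing carbon and a carboxylic ester group, and notably is *not* a
carboxylic acid (its single-bonded ring oxygen is a middle oxygen).
"""

from __future__ import annotations

from importlib import resources

from .chem_io import (
    DescriptionGraph,
    MolecularGraph,
    build_description_graph,
    parse_molfile,
    suppress_hydrogens,
)

__all__ = [
    "ASCORBIC_ACID_PREDICATE",
    "ascorbic_acid_molfile",
    "ascorbic_acid_graph",
    "ascorbic_acid_dg",
]

ASCORBIC_ACID_PREDICATE = "ascorbicAcid"


def ascorbic_acid_molfile() -> str:
    return (
        resources.files("chemrules").joinpath("data/ascorbic_acid.mol").read_text()
    )


def ascorbic_acid_graph() -> MolecularGraph:
    return parse_molfile(ascorbic_acid_molfile())


def ascorbic_acid_dg() -> DescriptionGraph:
    return build_description_graph(
        suppress_hydrogens(ascorbic_acid_graph()), ASCORBIC_ACID_PREDICATE
    )
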