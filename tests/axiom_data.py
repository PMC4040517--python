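"""Frozen reference pairs: surface axiom text ↔ expected rule translations.

The expected rules are written in the package's rule dialect; comparisons
are up to variable renaming and body-atom order.  The element predicates
are uniformly ``c``/``h`` (matching the structure vocabulary and the
worked stable model).
"""

AXIOM_RULE_PAIRS = [
    (
        "bond SuperPropertyOf single OR double OR triple",
        """
        bond(X, Y) :- single(X, Y).
        bond(X, Y) :- double(X, Y).
        bond(X, Y) :- triple(X, Y).
        """,
    ),
    (
        "charged SuperClassOf positive OR negative",
        """
        charged(X) :- negative(X).
        charged(X) :- positive(X).
        """,
    ),
    (
        "horc SuperClassOf h OR c",
        """
        horc(X) :- h(X).
        horc(X) :- c(X).
        """,
    ),
    (
        "carbonEntity SuperClassOf hasAtom SOME c",
        "carbonEntity(X) :- molecule(X), hasAtom(X, Y), c(Y).",
    ),
    (
        "polyatomicEntity SuperClassOf molecule AND "
        "( hasAtom SOME GraphNL ( DisjointNodes ( 1 , 2 ) Edges ( ) ) )",
        "polyatomicEntity(X) :- molecule(X), hasAtom(X, Y1), hasAtom(X, Y2), Y1 != Y2.",
    ),
    (
        "heteroOrganicEntity SuperClassOf hasAtom SOME GraphNL "
        "( Nodes ( 1 c , 2 NOT c NOT h ) Edges ( 1 2 bond ) )",
        "heteroOrganicEntity(X) :- hasAtom(X, Z1), hasAtom(X, Z2), c(Z1), "
        "bond(Z1, Z2), not c(Z2), not h(Z2).",
    ),
    (
        "middleOxygen SuperClassOf o AND "
        "( bond SOME GraphNL ( DisjointNodes ( 1 , 2 ) Edges ( ) ) )",
        "middleOxygen(Y1) :- hasAtom(X, Y1), hasAtom(X, Y2), hasAtom(X, Y3), "
        "o(Y1), bond(Y1, Y2), bond(Y1, Y3), Y2 != Y3.",
    ),
    (
        "carboxylicAcid SuperClassOf molecule AND ( hasAtom SOME GraphNL "
        "( Nodes ( 1 c , 2 o , 3 o NOT middleOxygen NOT charged , 4 horc ) "
        "Edges ( 1 2 double , 1 3 single , 1 4 single ) ) )",
        "carboxylicAcid(X) :- molecule(X), hasAtom(X, Y1), hasAtom(X, Y2), "
        "hasAtom(X, Y3), hasAtom(X, Y4), c(Y1), o(Y2), o(Y3), horc(Y4), "
        "double(Y1, Y2), single(Y1, Y3), single(Y1, Y4), "
        "not middleOxygen(Y3), not charged(Y3).",
    ),
    (
        "carboxylicEster SuperClassOf molecule AND ( hasAtom SOME Graph "
        "( Nodes ( 1 c , 2 o , 3 o , 4 c , 5 horc ) "
        "Edges ( 1 2 double , 1 3 single , 1 5 single , 3 4 single ) ) )",
        "carboxylicEster(X) :- molecule(X), hasAtom(X, Y1), hasAtom(X, Y2), "
        "hasAtom(X, Y3), hasAtom(X, Y4), hasAtom(X, Y5), c(Y1), c(Y4), "
        "o(Y2), o(Y3), horc(Y5), double(Y1, Y2), single(Y1, Y3), "
        "single(Y1, Y5), single(Y3, Y4).",
    ),
    (
        "exactly2Carbons SuperClassOf molecule AND hasAtom EXACTLY 2 c",
        """
        atLeast2Carbons(X) :- molecule(X), hasAtom(X, Y1), c(Y1), hasAtom(X, Y2), c(Y2), Y1 != Y2.
        atLeast3Carbons(X) :- molecule(X), hasAtom(X, Y1), c(Y1), hasAtom(X, Y2), c(Y2), hasAtom(X, Y3), c(Y3), Y1 != Y2, Y1 != Y3, Y2 != Y3.
        exactly2Carbons(X) :- atLeast2Carbons(X), not atLeast3Carbons(X).
        """,
    ),
    (
        "inorganic SuperClassOf molecule AND hasAtom ONLY ( NOT c )",
        "inorganic(X) :- molecule(X), not carbonEntity(X).",
    ),
    (
        "hydroCarbon SuperClassOf carbonEntity AND hasAtom ONLY ( h OR c )",
        """
        notHydroCarbon(X) :- hasAtom(X, Z), not c(Z), not h(Z).
        hydroCarbon(X) :- carbonEntity(X), not notHydroCarbon(X).
        """,
    ),
    (
        "unsaturated SuperClassOf molecule AND hasAtom SOME Graph "
        "( Nodes ( 1 c , 2 c ) Edges ( 1 2 double ) )",
        "unsaturated(X) :- molecule(X), hasAtom(X, Z1), c(Z1), hasAtom(X, Z2), "
        "c(Z2), double(Z1, Z2).",
    ),
    (
        "unsaturated SuperClassOf molecule AND hasAtom SOME Graph "
        "( Nodes ( 1 c , 2 c ) Edges ( 1 2 triple ) )",
        "unsaturated(X) :- molecule(X), hasAtom(X, Z1), c(Z1), hasAtom(X, Z2), "
        "c(Z2), triple(Z1, Z2).",
    ),
    (
        "saturated SuperClassOf molecule AND NOT unsaturated",
        "saturated(X) :- molecule(X), not unsaturated(X).",
    ),
    (
        "alkane SuperClassOf saturated AND hydroCarbon AND NOT cyclic",
        "alkane(X) :- saturated(X), hydroCarbon(X), not cyclic(X).",
    ),
]

# The structure axiom of the reference molecule: nodes 1-6 oxygen, 7-12
# carbon, 13 an explicitly kept hydrogen; 11 single + 2 double bonds.
ASCORBIC_AXIOM = (
    "ascorbicAcid SubClassOf molecule AND ( hasAtom SOME Graph ( "
    "Nodes ( 1 o , 2 o , 3 o , 4 o , 5 o , 6 o , 7 c , 8 c , 9 c , 10 c , "
    "11 c , 12 c , 13 h ) "
    "Edges ( 8 3 single , 9 4 single , 10 1 single , 10 9 single , "
    "10 11 single , 10 13 single , 12 5 single , 12 11 single , "
    "7 1 single , 7 8 single , 11 6 single , 2 7 double , 8 9 double ) ) )"
)
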