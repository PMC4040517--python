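"""Built-in chemical-class definitions.

The core registry covers four groups of class definitions:

* existence of subcomponents — carbonEntity, polyatomicEntity,
  heteroOrganicEntity, carboxylicAcid (with the middleOxygen helper),
  carboxylicEster;
* exact cardinality of parts — exactly2Carbons via
  atLeast2Carbons/atLeast3Carbons;
* exclusive composition — inorganic, hydroCarbon (with notHydroCarbon),
  unsaturated, saturated;
* cyclicity-related — cyclic and alkane.

All class definitions except ``cyclic`` are single-sourced from their
surface-syntax axioms (``CORE_SURFACE_TEXT``) and lowered at import; the
cyclic class is not expressible in surface syntax and is added directly as
rules (:func:`cyclicity_rules`).  ``inorganic`` follows the ChEBI
definition of inorganic molecular entities: no carbon atoms occur in them;
exceptions are the modeller's responsibility via extra rules.

A further set of ChEBI-style definitions (halogen compounds, amines,
aldehydes, ketones, single-atom entities) ships as a data file of surface
axioms.  Those are synthetic reconstructions from textual class
descriptions, are not validated by the test suite, and are excluded from
the core registry; load them explicitly with :func:`load_extra_classes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Union

from .logic import Atom, Inequality, Rule, Variable
from .surface import lower_axiom, parse_surface
from .translation import background_rules

__all__ = [
    "ClassDefinition",
    "UnknownClassError",
    "CORE_SURFACE_TEXT",
    "registry",
    "builtin_class_rules",
    "cyclicity_rules",
    "reported_class_predicates",
    "internal_predicates",
    "registry_manifest",
    "load_extra_classes",
    "CYCLICITY_CLASSES",
]


CORE_SURFACE_TEXT = """\
# Core chemical-class axioms (surface syntax).

carbonEntity SuperClassOf hasAtom SOME c

polyatomicEntity SuperClassOf molecule AND ( hasAtom SOME GraphNL ( DisjointNodes ( 1 , 2 ) Edges ( ) ) )

heteroOrganicEntity SuperClassOf hasAtom SOME GraphNL ( Nodes ( 1 c , 2 NOT c NOT h ) Edges ( 1 2 bond ) )

middleOxygen SuperClassOf o AND ( bond SOME GraphNL ( DisjointNodes ( 1 , 2 ) Edges ( ) ) )

carboxylicAcid SuperClassOf molecule AND ( hasAtom SOME GraphNL ( Nodes ( 1 c , 2 o , 3 o NOT middleOxygen NOT charged , 4 horc ) Edges ( 1 2 double , 1 3 single , 1 4 single ) ) )

# The ester pattern carries an explicit disjointness between the carbonyl
# carbon (1) and the alkyl atom (4): bond atoms are derived symmetrically,
# so without it the pattern would walk the 1-3 bond backwards (node 4
# collapsing onto node 1) and match every carboxylic acid.
carboxylicEster SuperClassOf molecule AND ( hasAtom SOME GraphNL ( Nodes ( 1 c , 2 o , 3 o , 4 c , 5 horc ) DisjointNodes ( 1 , 4 ) Edges ( 1 2 double , 1 3 single , 1 5 single , 3 4 single ) ) )

exactly2Carbons SuperClassOf molecule AND hasAtom EXACTLY 2 c

inorganic SuperClassOf molecule AND hasAtom ONLY ( NOT c )

hydroCarbon SuperClassOf carbonEntity AND hasAtom ONLY ( h OR c )

unsaturated SuperClassOf molecule AND hasAtom SOME Graph ( Nodes ( 1 c , 2 c ) Edges ( 1 2 double ) )

unsaturated SuperClassOf molecule AND hasAtom SOME Graph ( Nodes ( 1 c , 2 c ) Edges ( 1 2 triple ) )

saturated SuperClassOf molecule AND NOT unsaturated

alkane SuperClassOf saturated AND hydroCarbon AND NOT cyclic
"""


class UnknownClassError(KeyError):
    pass


@dataclass(frozen=True)
class ClassDefinition:
    """One registered chemical class: its rules and bookkeeping.

    ``reported`` marks molecule-level class predicates included in default
    classification output; atom-level helpers (middleOxygen) and internal
    predicates (the cyclicity ``reach`` relation) are hidden by default.
    """

    name: str
    group: str  # existence | cardinality | exclusive | cyclicity
    rules: frozenset[Rule]
    requires: tuple[str, ...] = ()
    reported: bool = True
    internal: frozenset[str] = frozenset()
    provenance: str = "core"


CYCLICITY_CLASSES = ("cyclic", "alkane")

_U, _V, _Y, _Z, _X = (Variable(n) for n in ("U", "V", "Y", "Z", "X"))


def cyclicity_rules() -> set[Rule]:
    """Rules deriving ``cyclic(x)`` iff the bond graph contains a ring.

    Edge-avoiding reachability: ``reach(u, v, y)`` holds when atom ``y`` is
    reachable from ``u`` along bond edges without traversing the undirected
    bond ``{u, v}``.  A molecule is cyclic iff some bond ``{u, v}`` can be
    closed into a ring, i.e. ``reach(u, v, v)`` holds.  The step guards
    spell out, as inequality conjunctions, that the step ``y → z`` does not
    traverse ``{u, v}`` in either direction; the first step from ``u`` only
    needs ``y ≠ v`` (bonds are irreflexive).
    """
    bond = lambda a, b: Atom("bond", (a, b))
    reach = lambda a, b, y: Atom("reach", (a, b, y))
    rules = {
        Rule.make(
            [bond(_U, _V), bond(_U, _Y), Inequality(_Y, _V)], [], reach(_U, _V, _Y)
        ),
        Rule.make(
            [Atom("hasAtom", (_X, _U)), bond(_U, _V), reach(_U, _V, _V)],
            [],
            Atom("cyclic", (_X,)),
        ),
    }
    step_guards = [
        (Inequality(_Y, _U), Inequality(_Y, _V)),
        (Inequality(_Y, _U), Inequality(_Z, _U)),
        (Inequality(_Z, _V), Inequality(_Y, _V)),
        (Inequality(_Z, _V), Inequality(_Z, _U)),
    ]
    for g1, g2 in step_guards:
        rules.add(
            Rule.make(
                [reach(_U, _V, _Y), bond(_Y, _Z), g1, g2], [], reach(_U, _V, _Z)
            )
        )
    return rules


def _core_definitions() -> dict[str, ClassDefinition]:
    axioms = parse_surface(CORE_SURFACE_TEXT)
    lowered: dict[str, set[Rule]] = {}
    for ax in axioms:
        for rule in lower_axiom(ax):
            lowered.setdefault(rule.head.predicate, set()).add(rule)

    def make(name, group, requires=(), reported=True, internal=frozenset()):
        return ClassDefinition(
            name,
            group,
            frozenset(lowered[name]),
            tuple(requires),
            reported,
            frozenset(internal),
        )

    defs = {
        "carbonEntity": make("carbonEntity", "existence"),
        "polyatomicEntity": make("polyatomicEntity", "existence"),
        "heteroOrganicEntity": make("heteroOrganicEntity", "existence"),
        "middleOxygen": make("middleOxygen", "existence", reported=False),
        "carboxylicAcid": make("carboxylicAcid", "existence", requires=("middleOxygen",)),
        "carboxylicEster": make("carboxylicEster", "existence"),
        "atLeast2Carbons": make("atLeast2Carbons", "cardinality"),
        "atLeast3Carbons": make("atLeast3Carbons", "cardinality"),
        "exactly2Carbons": make(
            "exactly2Carbons",
            "cardinality",
            requires=("atLeast2Carbons", "atLeast3Carbons"),
        ),
        "inorganic": make("inorganic", "exclusive", requires=("carbonEntity",)),
        "notHydroCarbon": make("notHydroCarbon", "exclusive"),
        "hydroCarbon": make(
            "hydroCarbon", "exclusive", requires=("carbonEntity", "notHydroCarbon")
        ),
        "unsaturated": make("unsaturated", "exclusive"),
        "saturated": make("saturated", "exclusive", requires=("unsaturated",)),
        "cyclic": ClassDefinition(
            "cyclic",
            "cyclicity",
            frozenset(cyclicity_rules()),
            internal=frozenset({"reach"}),
        ),
        "alkane": ClassDefinition(
            "alkane",
            "cyclicity",
            frozenset(lowered["alkane"]),
            requires=("saturated", "hydroCarbon", "cyclic"),
        ),
    }
    return defs


@lru_cache(maxsize=1)
def registry() -> dict[str, ClassDefinition]:
    return _core_definitions()


def _resolve(names: Iterable[str]) -> list[ClassDefinition]:
    reg = registry()
    seen: dict[str, ClassDefinition] = {}
    stack = list(names)
    while stack:
        name = stack.pop()
        if name in seen:
            continue
        if name not in reg:
            raise UnknownClassError(name)
        d = reg[name]
        seen[name] = d
        stack.extend(d.requires)
    return [seen[n] for n in sorted(seen)]


def _selection(names: Union[str, Iterable[str]], with_cyclic: bool) -> list[str]:
    reg = registry()
    if names == "all":
        selected = sorted(reg)
    elif names == "no-cyclic":
        selected = sorted(n for n in reg if reg[n].group != "cyclicity")
    elif isinstance(names, str):
        raise UnknownClassError(names)
    else:
        selected = sorted(set(names))
    if not with_cyclic:
        selected = [
            n for n in selected if n in reg and reg[n].group != "cyclicity"
        ] + [n for n in selected if n not in reg]
    return selected


def builtin_class_rules(
    names: Union[str, Iterable[str]] = "all", with_cyclic: bool = True
) -> set[Rule]:
    """Union of the requested class definitions, their prerequisites, and
    the background rules.

    ``names`` is ``"all"``, ``"no-cyclic"`` or an iterable of class names;
    ``with_cyclic=False`` additionally drops the cyclicity group (the
    cheaper 'no cyclic' evaluation mode).  Requesting an empty selection
    returns the background rules only.
    """
    rules = set(background_rules())
    for d in _resolve(_selection(names, with_cyclic)):
        rules |= d.rules
    return rules


def reported_class_predicates(
    names: Union[str, Iterable[str]] = "all", with_cyclic: bool = True
) -> frozenset[str]:
    """Class predicates included in default classification output."""
    return frozenset(
        d.name for d in _resolve(_selection(names, with_cyclic)) if d.reported
    )


def all_class_predicates(
    names: Union[str, Iterable[str]] = "all", with_cyclic: bool = True
) -> frozenset[str]:
    """Reported classes plus hidden helpers (but never internal relations)."""
    preds: set[str] = set()
    for d in _resolve(_selection(names, with_cyclic)):
        preds.add(d.name)
    return frozenset(preds)


def internal_predicates() -> frozenset[str]:
    preds: set[str] = set()
    for d in registry().values():
        preds |= d.internal
    return frozenset(preds)


def registry_manifest() -> list[dict]:
    """name → group → provenance rows, for serializing the registry."""
    return [
        {
            "name": d.name,
            "group": d.group,
            "provenance": d.provenance,
            "reported": d.reported,
            "requires": ",".join(d.requires),
        }
        for d in sorted(registry().values(), key=lambda d: (d.group, d.name))
    ]


def load_extra_classes() -> set[Rule]:
    """Lower the shipped reconstructed (synthetic, unvalidated) extra axioms."""
    text = (
        resources.files("chemrules")
        .joinpath("data/extra_classes_synthetic.surface")
        .read_text()
    )
    rules: set[Rule] = set()
    for ax in parse_surface(text):
        rules |= lower_axiom(ax)
    return rules
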