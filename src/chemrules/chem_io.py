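"""MDL molfile (V2000) parsing and description-graph construction.

A molecule enters the pipeline as a connection table, becomes a
:class:`MolecularGraph` (atoms with formal charges, bonds with orders and
stereo flags), is hydrogen-suppressed under the implicit-hydrogen
convention, and is finally abstracted into a :class:`DescriptionGraph`: a
labeled graph with an (implicit) molecule root node linked by ``hasAtom``
to every atom node, element/charge labels on atom nodes, and
single/double/triple labels on bond edges.

Only the V2000 dialect is supported; V3000 input is rejected.  Aromatic
bond codes are rejected rather than kekulized — structures must arrive
kekulized, since the bond vocabulary is exactly {single, double, triple}.
Coordinates are read and ignored.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

__all__ = [
    "AtomRecord",
    "BondRecord",
    "MolecularGraph",
    "DescriptionGraph",
    "MolfileParseError",
    "UnsupportedElementError",
    "HydrogenSuppressionWarning",
    "parse_molfile",
    "parse_sdf",
    "suppress_hydrogens",
    "build_description_graph",
    "BOND_ORDER_LABELS",
]


BOND_ORDER_LABELS = {1: "single", 2: "double", 3: "triple"}

# IUPAC element symbols (through oganesson).
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

# Atom-block charge codes (field 4): 0 none, 1..3 = +3..+1, 4 = radical, 5..7 = -1..-3
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}


class MolfileParseError(ValueError):
    """Structured parse failure naming the offending molfile line."""

    def __init__(self, message: str, line: int):
        super().__init__(f"molfile line {line}: {message}")
        self.line = line


class UnsupportedElementError(ValueError):
    def __init__(self, symbol: str):
        super().__init__(f"unsupported element symbol: {symbol!r}")
        self.symbol = symbol


class HydrogenSuppressionWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AtomRecord:
    index: int  # 1-based ordinal within the molecule
    element: str
    formal_charge: int = 0


@dataclass(frozen=True)
class BondRecord:
    from_idx: int
    to_idx: int
    order: int  # 1 single, 2 double, 3 triple
    stereo_flag: int = 0  # 0 plain; nonzero wedge/hash annotation

    def pair(self) -> tuple[int, int]:
        return (min(self.from_idx, self.to_idx), max(self.from_idx, self.to_idx))


@dataclass(frozen=True)
class MolecularGraph:
    name: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, index: int) -> int:
        return sum(1 for b in self.bonds if index in (b.from_idx, b.to_idx))


@dataclass(frozen=True)
class DescriptionGraph:
    """Labeled graph abstraction of one (hydrogen-suppressed) molecule.

    Node 0 — the molecule node, labeled with the molecule predicate and
    implicitly linked to every atom node by ``hasAtom`` — is not stored;
    ``atom_nodes`` maps node index (1..n) to its label set (exactly one
    lowercased element predicate, optionally ``positive``/``negative``) and
    ``bond_edges`` holds one ``(i, j, order-label)`` per unordered bond with
    i < j.
    """

    molecule_predicate: str
    atom_nodes: dict[int, frozenset[str]]
    bond_edges: frozenset[tuple[int, int, str]]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_nodes)

    def element_label(self, index: int) -> str:
        labels = self.atom_nodes[index] - {"positive", "negative"}
        (label,) = labels
        return label


def _int_field(line: str, start: int, end: int, lineno: int, what: str) -> int:
    raw = line[start:end].strip()
    try:
        return int(raw)
    except ValueError:
        raise MolfileParseError(f"malformed {what}: {raw!r}", lineno) from None


def parse_molfile(text: str, name: str | None = None) -> MolecularGraph:
    """Parse a single V2000 molfile into a :class:`MolecularGraph`.

    ``M  CHG`` property lines, when present, supersede the atom-block charge
    column (all atom-block codes are reset first, per the MDL convention).
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("molfile has no counts line", len(lines) or 1)
    title = (name if name is not None else lines[0].strip()) or "unnamed"
    counts_line, counts_no = lines[3], 4
    if "V3000" in counts_line:
        raise MolfileParseError("V3000 connection tables are not supported", counts_no)
    n_atoms = _int_field(counts_line, 0, 3, counts_no, "atom count")
    n_bonds = _int_field(counts_line, 3, 6, counts_no, "bond count")

    atom_lines = lines[4 : 4 + n_atoms]
    if len(atom_lines) < n_atoms:
        raise MolfileParseError(
            f"atom block truncated: expected {n_atoms} atoms", len(lines)
        )
    atoms: list[AtomRecord] = []
    for i, line in enumerate(atom_lines):
        lineno = 5 + i
        fields = line.split()
        symbol = line[31:34].strip() or (fields[3] if len(fields) > 3 else "")
        if not symbol:
            raise MolfileParseError("missing element symbol", lineno)
        code = 0
        raw_code = line[36:39].strip()
        if raw_code:
            try:
                code = int(raw_code)
            except ValueError:
                raise MolfileParseError(f"malformed charge code {raw_code!r}", lineno)
        charge = _CHARGE_CODES.get(code, 0)
        atoms.append(AtomRecord(index=i + 1, element=symbol, formal_charge=charge))

    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(bond_lines) < n_bonds:
        raise MolfileParseError(
            f"bond block truncated: expected {n_bonds} bonds", len(lines)
        )
    bonds: list[BondRecord] = []
    seen_pairs: set[tuple[int, int]] = set()
    for i, line in enumerate(bond_lines):
        lineno = 5 + n_atoms + i
        a1 = _int_field(line, 0, 3, lineno, "bond atom index")
        a2 = _int_field(line, 3, 6, lineno, "bond atom index")
        order = _int_field(line, 6, 9, lineno, "bond order")
        stereo = 0
        raw_stereo = line[9:12].strip()
        if raw_stereo:
            try:
                stereo = int(raw_stereo)
            except ValueError:
                raise MolfileParseError(f"malformed stereo flag {raw_stereo!r}", lineno)
        if order not in BOND_ORDER_LABELS:
            raise MolfileParseError(
                f"unsupported bond order {order} (only 1/2/3; aromatic input "
                "must be kekulized)",
                lineno,
            )
        if a1 == a2:
            raise MolfileParseError(f"self-bond on atom {a1}", lineno)
        for idx in (a1, a2):
            if not 1 <= idx <= n_atoms:
                raise MolfileParseError(f"dangling bond atom index {idx}", lineno)
        pair = (min(a1, a2), max(a1, a2))
        if pair in seen_pairs:
            raise MolfileParseError(f"parallel bond between atoms {pair}", lineno)
        seen_pairs.add(pair)
        bonds.append(BondRecord(a1, a2, order, stereo))

    # Property block: "M  CHG" overrides all atom-block charge codes.
    chg_entries: list[tuple[int, int]] = []
    saw_chg = False
    for j, line in enumerate(lines[4 + n_atoms + n_bonds :]):
        lineno = 5 + n_atoms + n_bonds + j
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            saw_chg = True
            fields = line.split()
            try:
                count = int(fields[2])
                pairs = [(int(fields[3 + 2 * k]), int(fields[4 + 2 * k])) for k in range(count)]
            except (IndexError, ValueError):
                raise MolfileParseError("malformed M  CHG line", lineno) from None
            for idx, value in pairs:
                if not 1 <= idx <= n_atoms:
                    raise MolfileParseError(f"M  CHG names unknown atom {idx}", lineno)
                chg_entries.append((idx, value))
    if saw_chg:
        atoms = [AtomRecord(a.index, a.element, 0) for a in atoms]
        for idx, value in chg_entries:
            a = atoms[idx - 1]
            atoms[idx - 1] = AtomRecord(a.index, a.element, value)

    return MolecularGraph(name=title, atoms=tuple(atoms), bonds=tuple(bonds))


def parse_sdf(text: str) -> list[MolecularGraph]:
    """Parse a multi-record SDF; records are separated by ``$$$$`` lines."""
    records = re.split(r"^\$\$\$\$\s*$", text, flags=re.MULTILINE)
    graphs = []
    for rec in records:
        if rec.strip():
            graphs.append(parse_molfile(rec.lstrip("\n")))
    return graphs


def suppress_hydrogens(g: MolecularGraph) -> MolecularGraph:
    """Drop implicit-convention hydrogens; keep stereo-annotated ones.

    A hydrogen atom is removed iff it has exactly one incident bond and that
    bond carries no stereo annotation.  Hydrogens with two or more bonds are
    kept and reported via :class:`HydrogenSuppressionWarning` (never
    silently dropped).  Remaining atoms are renumbered contiguously in their
    original order.
    """
    degree: dict[int, int] = {a.index: 0 for a in g.atoms}
    incident: dict[int, list[BondRecord]] = {a.index: [] for a in g.atoms}
    for b in g.bonds:
        degree[b.from_idx] += 1
        degree[b.to_idx] += 1
        incident[b.from_idx].append(b)
        incident[b.to_idx].append(b)

    removed: set[int] = set()
    for a in g.atoms:
        if a.element != "H":
            continue
        if degree[a.index] > 1:
            warnings.warn(
                f"{g.name}: hydrogen atom {a.index} has {degree[a.index]} bonds; kept",
                HydrogenSuppressionWarning,
                stacklevel=2,
            )
            continue
        if degree[a.index] == 1 and incident[a.index][0].stereo_flag == 0:
            removed.add(a.index)

    if not removed:
        return g
    remap: dict[int, int] = {}
    kept_atoms = []
    for a in g.atoms:
        if a.index not in removed:
            remap[a.index] = len(kept_atoms) + 1
            kept_atoms.append(AtomRecord(len(kept_atoms) + 1, a.element, a.formal_charge))
    kept_bonds = [
        BondRecord(remap[b.from_idx], remap[b.to_idx], b.order, b.stereo_flag)
        for b in g.bonds
        if b.from_idx not in removed and b.to_idx not in removed
    ]
    return MolecularGraph(g.name, tuple(kept_atoms), tuple(kept_bonds))


def build_description_graph(g: MolecularGraph, molecule_predicate: str) -> DescriptionGraph:
    """Abstract a (hydrogen-suppressed) molecular graph into its DG.

    Atom nodes are labeled with the lowercased element predicate plus
    ``positive``/``negative`` for nonzero formal charges; bond orders map to
    single/double/triple edge labels, one edge per unordered pair.
    """
    nodes: dict[int, frozenset[str]] = {}
    for a in g.atoms:
        if a.element not in ELEMENT_SYMBOLS:
            raise UnsupportedElementError(a.element)
        labels = {a.element.lower()}
        if a.formal_charge > 0:
            labels.add("positive")
        elif a.formal_charge < 0:
            labels.add("negative")
        nodes[a.index] = frozenset(labels)
    edges = frozenset(
        (*b.pair(), BOND_ORDER_LABELS[b.order]) for b in g.bonds
    )
    return DescriptionGraph(molecule_predicate, nodes, edges)
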