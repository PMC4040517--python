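"""Seeded generator of synthetic molecules with independent ground truth.

Generated molecules are connected, respect valence caps (C ≤ 4, O ≤ 2,
N ≤ 3, H ≤ 1, counting bond orders), optionally contain a ring (a ring of
3–6 carbons is built first, then the remaining atoms attach as a tree — so
``ring_probability=1`` guarantees a cycle and ``ring_probability=0``
guarantees a forest), may carry a −1 charge on a terminal oxygen, and may
have a few explicit hydrogens, occasionally on a stereo-annotated bond so
that hydrogen suppression keeps them.

Ground truth (cyclicity, carbon count, element multiset, carboxy-group
presence, saturation, ...) is computed by direct graph algorithms on the
generator's own structures — never by the rule engine — so that
engine-versus-ground-truth comparisons are meaningful tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

__all__ = ["FixtureSpec", "SyntheticMolecule", "generate_fixtures", "ground_truth_frame"]


VALENCE_CAPS = {"C": 4, "O": 2, "N": 3, "H": 1}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one batch of synthetic molecules.

    Defaults emulate small organic compounds: 1–10 heavy atoms drawn from a
    carbon-rich C/O/N alphabet, about a third of molecules carrying a ring,
    occasional charged terminal oxygens and explicit hydrogens.
    """

    seed: int
    n_molecules: int = 10
    min_atoms: int = 1
    max_atoms: int = 10
    elements: tuple[str, ...] = ("C", "C", "C", "C", "O", "N")
    ring_probability: float = 0.3
    charge_probability: float = 0.1
    double_bond_probability: float = 0.15
    explicit_h_probability: float = 0.3
    stereo_h_probability: float = 0.1

    def __post_init__(self) -> None:
        if self.min_atoms < 1 or self.max_atoms < self.min_atoms:
            raise ValueError("need 1 <= min_atoms <= max_atoms")
        bad = set(self.elements) - set(VALENCE_CAPS) | {"H"} & set(self.elements)
        if bad:
            raise ValueError(f"unsupported heavy-atom elements: {sorted(bad)}")


@dataclass(frozen=True)
class SyntheticMolecule:
    name: str
    molfile: str
    # ground truth on the hydrogen-suppressed view:
    cyclic: bool
    n_carbons: int
    element_multiset: str
    has_carboxy: bool
    saturated: bool
    hydrocarbon: bool
    inorganic: bool
    polyatomic: bool
    n_suppressed_atoms: int


def _spare(caps, orders_sum, i) -> int:
    return caps[i] - orders_sum[i]


def _build_one(rng: random.Random, spec: FixtureSpec, name: str) -> SyntheticMolecule:
    n = rng.randint(spec.min_atoms, spec.max_atoms)
    want_ring = rng.random() < spec.ring_probability
    if want_ring:
        n = max(n, 3)

    elements: list[str] = []
    bonds: list[list[int]] = []  # [i, j, order, stereo], 0-based indices

    if want_ring:
        ring_size = rng.randint(3, min(n, 6))
        elements.extend("C" * ring_size)
        for k in range(ring_size):
            bonds.append([k, (k + 1) % ring_size, 1, 0])
    else:
        elements.append(rng.choice(spec.elements))

    caps = {i: VALENCE_CAPS[e] for i, e in enumerate(elements)}
    orders_sum = {i: 0 for i in caps}
    for i, j, order, _ in bonds:
        orders_sum[i] += order
        orders_sum[j] += order

    while len(elements) < n:
        attach_points = [i for i in caps if _spare(caps, orders_sum, i) >= 1]
        if not attach_points:
            break  # valence-saturated; accept a smaller molecule
        parent = rng.choice(attach_points)
        elem = rng.choice(spec.elements)
        idx = len(elements)
        elements.append(elem)
        caps[idx] = VALENCE_CAPS[elem]
        orders_sum[idx] = 0
        bonds.append([parent, idx, 1, 0])
        orders_sum[parent] += 1
        orders_sum[idx] += 1

    # Upgrade some bonds to double where valence allows (C=C and C=O).
    for b in bonds:
        i, j, order, _ = b
        pair = {elements[i], elements[j]}
        if order == 1 and pair <= {"C", "O"} and "C" in pair:
            if _spare(caps, orders_sum, i) >= 1 and _spare(caps, orders_sum, j) >= 1:
                if rng.random() < spec.double_bond_probability:
                    b[2] = 2
                    orders_sum[i] += 1
                    orders_sum[j] += 1

    # Charge: a terminal single-bonded oxygen may be an anion.
    charges = {i: 0 for i in range(len(elements))}
    if rng.random() < spec.charge_probability:
        terminal_o = [
            i
            for i in range(len(elements))
            if elements[i] == "O" and orders_sum[i] == 1
        ]
        if terminal_o:
            charges[rng.choice(terminal_o)] = -1

    # Explicit hydrogens (suppressible unless stereo-flagged).
    if rng.random() < spec.explicit_h_probability:
        candidates = [
            i for i in range(len(elements))
            if elements[i] != "H" and _spare(caps, orders_sum, i) >= 1 and charges[i] == 0
        ]
        for parent in rng.sample(candidates, min(len(candidates), rng.randint(1, 2))):
            idx = len(elements)
            elements.append("H")
            caps[idx] = 1
            orders_sum[idx] = 0
            charges[idx] = 0
            stereo = 1 if rng.random() < spec.stereo_h_probability else 0
            bonds.append([parent, idx, 1, stereo])
            orders_sum[parent] += 1
            orders_sum[idx] += 1

    return _finish(name, elements, bonds, charges)


def _finish(name, elements, bonds, charges) -> SyntheticMolecule:
    # Hydrogen-suppressed view, mirroring the implicit-hydrogen convention:
    # drop H atoms of degree one on stereo-free bonds.
    degree = {i: 0 for i in range(len(elements))}
    for i, j, _, _ in bonds:
        degree[i] += 1
        degree[j] += 1
    suppressed = {
        i
        for i in range(len(elements))
        if elements[i] == "H"
        and degree[i] == 1
        and next(b for b in bonds if i in (b[0], b[1]))[3] == 0
    }
    kept = [i for i in range(len(elements)) if i not in suppressed]
    kept_bonds = [b for b in bonds if b[0] not in suppressed and b[1] not in suppressed]

    graph = nx.Graph()
    graph.add_nodes_from(kept)
    graph.add_edges_from((b[0], b[1]) for b in kept_bonds)
    cyclic = bool(kept) and not nx.is_forest(graph)

    kept_elems = [elements[i] for i in kept]
    n_carbons = kept_elems.count("C")
    counts = {}
    for e in kept_elems:
        counts[e] = counts.get(e, 0) + 1
    multiset = " ".join(f"{e}{counts[e]}" for e in sorted(counts))

    saturated = not any(
        b[2] >= 2 and elements[b[0]] == "C" and elements[b[1]] == "C"
        for b in kept_bonds
    )

    sup_degree = {i: 0 for i in kept}
    for b in kept_bonds:
        sup_degree[b[0]] += 1
        sup_degree[b[1]] += 1

    def neighbors(i):
        for b in kept_bonds:
            if b[0] == i:
                yield b[1], b[2]
            elif b[1] == i:
                yield b[0], b[2]

    has_carboxy = False
    for i in kept:
        if elements[i] != "C":
            continue
        dbl_o = [j for j, o in neighbors(i) if elements[j] == "O" and o == 2]
        single_o = [
            j
            for j, o in neighbors(i)
            if elements[j] == "O"
            and o == 1
            and sup_degree[j] == 1
            and charges[j] == 0
        ]
        others = [
            j for j, o in neighbors(i) if elements[j] in ("C", "H") and o == 1
        ]
        if dbl_o and single_o and others:
            has_carboxy = True
            break

    has_carbon = n_carbons > 0
    hydrocarbon = has_carbon and all(e in ("C", "H") for e in kept_elems)
    inorganic = not has_carbon
    polyatomic = len(kept) >= 2

    return SyntheticMolecule(
        name=name,
        molfile=_write_molfile(name, elements, bonds, charges),
        cyclic=cyclic,
        n_carbons=n_carbons,
        element_multiset=multiset,
        has_carboxy=has_carboxy,
        saturated=saturated,
        hydrocarbon=hydrocarbon,
        inorganic=inorganic,
        polyatomic=polyatomic,
        n_suppressed_atoms=len(kept),
    )


def _write_molfile(name, elements, bonds, charges) -> str:
    lines = [name, "  chemrules synthetic", "", f"{len(elements):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000"]
    for e in elements:
        lines.append(f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {e:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order, stereo in bonds:
        lines.append(f"{i + 1:>3}{j + 1:>3}{order:>3}{stereo:>3}  0  0  0")
    charged = [(i + 1, c) for i, c in sorted(charges.items()) if c != 0]
    for k in range(0, len(charged), 8):
        chunk = charged[k : k + 8]
        entries = "".join(f" {idx:>3} {val:>3}" for idx, val in chunk)
        lines.append(f"M  CHG  {len(chunk)}{entries}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def generate_fixtures(spec: FixtureSpec) -> list[SyntheticMolecule]:
    """Reproducibly generate ``spec.n_molecules`` synthetic molecules."""
    rng = random.Random(spec.seed)
    return [
        _build_one(rng, spec, f"synth{k:04d}") for k in range(spec.n_molecules)
    ]


def ground_truth_frame(molecules: list[SyntheticMolecule]) -> pd.DataFrame:
    """Ground-truth table, one row per molecule."""
    return pd.DataFrame(
        [
            {
                "molecule_id": m.name,
                "cyclic": m.cyclic,
                "n_carbons": m.n_carbons,
                "element_multiset": m.element_multiset,
                "has_carboxy": m.has_carboxy,
                "saturated": m.saturated,
                "hydrocarbon": m.hydrocarbon,
                "inorganic": m.inorganic,
                "polyatomic": m.polyatomic,
            }
            for m in molecules
        ]
    )
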