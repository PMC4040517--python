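"""Six-stage classification pipeline.

1. parse molfiles, 2. compile the knowledge base (structure rules + seed
facts + class rules, partitioned into modules of a configurable number of
molecules), 3. termination check per module, 4. stable-model computation,
5. optional model storage, 6. subsumption extraction to CSV.

Classification output is invariant under the module partitioning: each
module carries the full class rule set and the structure rules of its own
molecules, and molecules interact only through their private skolem terms,
so merging per-module results equals the unpartitioned run.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import pandas as pd

from . import classes as chemclasses
from .chem_io import (
    DescriptionGraph,
    MolecularGraph,
    build_description_graph,
    parse_molfile,
    suppress_hydrogens,
)
from .engine import check_termination, compute_stable_model
from .logic import Atom, Constant, FunctionalTerm, Program, StableModel, format_atom
from .translation import dg_to_structure_rules, molecule_seed_fact

__all__ = [
    "ClassificationResult",
    "PipelineAbort",
    "DEFAULT_MODULE_SIZE",
    "DEFAULT_MODULE_SIZE_WITH_CYCLIC",
    "sanitize_molecule_name",
    "classify_molecules",
    "extract_subsumptions",
    "write_subsumptions_csv",
    "read_subsumptions_csv",
    "dump_model",
]

logger = logging.getLogger("chemrules")

# Module sizes with the shortest observed end-to-end times for the two modes.
DEFAULT_MODULE_SIZE = 50
DEFAULT_MODULE_SIZE_WITH_CYCLIC = 20


class PipelineAbort(RuntimeError):
    """Raised when a module fails the termination check (stage 3)."""


@dataclass
class ClassificationResult:
    """Molecule → sorted chemical-class subsumers, plus run bookkeeping."""

    assignments: dict[str, tuple[str, ...]]
    partition: dict[str, int] = field(default_factory=dict)
    stage_log: list[tuple[str, str, float]] = field(default_factory=list)

    def pairs(self) -> set[tuple[str, str]]:
        return {
            (mol, cls) for mol, classes in self.assignments.items() for cls in classes
        }


def sanitize_molecule_name(title: str) -> str:
    """Molfile title → molecule predicate (lower-case initial identifier)."""
    cleaned = re.sub(r"[^A-Za-z0-9]", "_", title.strip()) or "unnamed"
    if cleaned[0].isdigit():
        cleaned = "m" + cleaned
    return cleaned[0].lower() + cleaned[1:]


def _unique_names(titles: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for t in titles:
        base = sanitize_molecule_name(t)
        if base in seen:
            seen[base] += 1
            out.append(f"{base}_{seen[base]}")
        else:
            seen[base] = 1
            out.append(base)
    return out


def _graph_has_ring(g: MolecularGraph) -> bool:
    nxg = nx.Graph()
    nxg.add_nodes_from(a.index for a in g.atoms)
    nxg.add_edges_from((b.from_idx, b.to_idx) for b in g.bonds)
    return g.n_atoms > 0 and not nx.is_forest(nxg)


def classify_molecules(
    molfiles: Iterable[Union[str, MolecularGraph]],
    classes: Union[str, Iterable[str]] = "all",
    module_size: Optional[int] = None,
    *,
    include_aux: bool = False,
    fast_cyclic: bool = False,
    check: bool = True,
    dump_model_path: Optional[Union[str, Path]] = None,
) -> ClassificationResult:
    """Run the full pipeline on molfile texts (or pre-parsed graphs).

    ``classes`` selects registered class definitions (``"all"``,
    ``"no-cyclic"`` or explicit names); ``module_size`` is the number of
    molecules per evaluation module (defaults to the mode-specific optimum);
    ``fast_cyclic`` computes ring membership graph-theoretically and injects
    ``cyclic`` facts instead of deriving them by rules; ``check=False``
    skips the per-module termination check.
    """
    result = ClassificationResult({})

    def log_stage(stage: str, detail: str, t0: float) -> None:
        dt = time.perf_counter() - t0
        result.stage_log.append((stage, detail, dt))
        logger.info("%s: %s (%.3fs)", stage, detail, dt)

    # Stage 1: parsing.
    t0 = time.perf_counter()
    graphs: list[MolecularGraph] = []
    for item in molfiles:
        graphs.append(item if isinstance(item, MolecularGraph) else parse_molfile(item))
    names = _unique_names([g.name for g in graphs])
    log_stage("parse", f"{len(graphs)} molecules", t0)

    # Stage 2: KB compilation.
    t0 = time.perf_counter()
    class_rules = chemclasses.builtin_class_rules(classes)
    selected = chemclasses.all_class_predicates(classes)
    cyclic_selected = "cyclic" in selected
    if fast_cyclic and cyclic_selected:
        class_rules -= chemclasses.registry()["cyclic"].rules

    dgs: list[DescriptionGraph] = []
    ring_flags: list[bool] = []
    for g, name in zip(graphs, names):
        suppressed = suppress_hydrogens(g)
        dgs.append(build_description_graph(suppressed, name))
        ring_flags.append(_graph_has_ring(suppressed))

    if module_size is None:
        module_size = (
            DEFAULT_MODULE_SIZE_WITH_CYCLIC if cyclic_selected else DEFAULT_MODULE_SIZE
        )
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    modules = [
        list(range(i, min(i + module_size, len(dgs))))
        for i in range(0, len(dgs), module_size)
    ]
    log_stage("compile", f"{len(class_rules)} class rules, {len(modules)} modules", t0)

    constants = {names[i]: Constant(f"m{i}") for i in range(len(dgs))}
    reported = (
        chemclasses.all_class_predicates(classes)
        if include_aux
        else chemclasses.reported_class_predicates(classes)
    )

    assignments: dict[str, tuple[str, ...]] = {}
    partition: dict[str, int] = {}
    all_facts: list[Atom] = []
    used_constants: set[str] = set()
    for mod_idx, member_ids in enumerate(modules):
        rules = set(class_rules)
        facts = set()
        module_constants = {}
        for i in member_ids:
            rules |= dg_to_structure_rules(dgs[i])
            seed = molecule_seed_fact(names[i], constants[names[i]].name, used_constants)
            used_constants.add(constants[names[i]].name)
            facts.add(seed)
            module_constants[names[i]] = constants[names[i]]
            partition[names[i]] = mod_idx
            if fast_cyclic and cyclic_selected and ring_flags[i]:
                facts.add(Atom("cyclic", (constants[names[i]],)))
        program = Program.make(rules, facts)

        # Stage 3: termination check.
        if check:
            t0 = time.perf_counter()
            report = check_termination(program)
            log_stage("check", f"module {mod_idx}: {'pass' if report.passed else 'FAIL'}", t0)
            if not report.passed:
                raise PipelineAbort(
                    f"module {mod_idx} failed the termination check "
                    f"(witness: {report.witness_text()}); aborting before "
                    "model computation"
                )

        # Stage 4: model computation.
        t0 = time.perf_counter()
        model = compute_stable_model(program, check=False)
        log_stage("evaluate", f"module {mod_idx}: {len(model)} facts", t0)

        # Stage 6 (per module): subsumption extraction.
        pairs = extract_subsumptions(model, module_constants, reported)
        for name in module_constants:
            classes_of = sorted(c for (m, c) in pairs if m == name)
            assignments[name] = tuple(classes_of)
        if dump_model_path is not None:
            all_facts.extend(model.facts)

    # Stage 5: model storage (optional).
    if dump_model_path is not None:
        t0 = time.perf_counter()
        dump_model(StableModel(frozenset(all_facts)), dump_model_path)
        log_stage("store", str(dump_model_path), t0)

    result.assignments = assignments
    result.partition = partition
    return result


def extract_subsumptions(
    model: StableModel,
    constants: dict[str, Constant],
    class_predicates: Iterable[str],
) -> set[tuple[str, str]]:
    """(molecule, class) pairs: ``C(const) ∈ model`` for registered classes.

    Facts over skolem terms (atom-level helpers, when included) are
    attributed to the molecule whose constant they are built on.
    """
    by_constant = {c: name for name, c in constants.items()}
    pairs: set[tuple[str, str]] = set()
    preds = set(class_predicates)
    for fact in model.facts:
        if fact.predicate not in preds or len(fact.args) != 1:
            continue
        term = fact.args[0]
        while isinstance(term, FunctionalTerm):
            term = term.arg
        name = by_constant.get(term)
        if name is not None:
            pairs.add((name, fact.predicate))
    return pairs


def write_subsumptions_csv(result: ClassificationResult, path: Union[str, Path]) -> None:
    """Store subsumee–subsumer pairs as a sorted two-column CSV."""
    rows = sorted(result.pairs())
    frame = pd.DataFrame(rows, columns=["molecule_id", "class_name"])
    frame.to_csv(path, index=False)


def read_subsumptions_csv(path: Union[str, Path]) -> set[tuple[str, str]]:
    frame = pd.read_csv(path)
    return {(r.molecule_id, r.class_name) for r in frame.itertuples()}


def dump_model(model: StableModel, path: Union[str, Path]) -> None:
    """One ground fact per line in the rule dialect, sorted."""
    Path(path).write_text(
        "".join(format_atom(f) + ".\n" for f in model.sorted_facts())
    )
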