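# Methods

## Problem and model

`chemrules` performs structure-based classification of molecules under
chemical-class definitions, in the style of rule-based ontology reasoning
over ChEBI-like class descriptions. A molecule's connection table (MDL
molfile V2000) is abstracted into a *description graph* (DG): a labeled
graph with one node per atom plus a root molecule node, `hasAtom` edges
from the root to every atom node, element (and charge) labels on atom
nodes, and single/double/triple labels on bond edges. The DG is unfolded
into *nonmonotonic existential rules*: instantiating the molecule
predicate creates one skolem term `f_i(x)` per atom node, types it with
its labels, and relates bonded atoms. Chemical classes are rules over this
vocabulary, possibly with negation as failure (closed-world reading) and
inequalities; many of them — inorganic or saturated compounds,
hydrocarbons, rings of arbitrary length — are not expressible in
description logics precisely because they need negation or cycles.

Classification evaluates the combined program (structure rules + seed
facts + class rules) under **stable model semantics** and reads off the
class facts over the molecule constants. All packaged programs are
*stratified*, so the stable model is unique and computable bottom-up.

## Conventions and assumptions

* **Implicit hydrogens.** Hydrogen atoms with a single, stereo-free bond
  are suppressed before DG construction; hydrogens on stereo-annotated
  bonds are kept (and a multiply-bonded hydrogen is kept with a warning).
  Consequences are semantic, not merely representational: a suppressed-to-
  one-atom molecule (water, methane) is not `polyatomicEntity`, and the
  carboxy pattern requires its fourth neighbour (`horc`) to be an explicit
  node, so formic acid — whose fourth neighbour is a suppressed H — is not
  recognised. The class definitions compensate where possible: the
  carboxylic-acid pattern guards its hydroxy oxygen with
  `not middleOxygen` and `not charged` because O and OH are
  indistinguishable after suppression.
* **Bond symmetry.** Bond-order atoms are derived in both directions for
  every DG edge, so pattern matching never depends on the arbitrary atom
  ordering of the input molfile; `hasAtom` stays directed. Reporting and
  tests canonicalize bonds to unordered pairs. One consequence: patterns
  that re-traverse an edge backwards can collapse two pattern nodes onto
  the same atom, so the built-in carboxylic-ester definition carries an
  explicit disjointness between the carbonyl carbon and the ester-alkyl
  atom (without it, every carboxylic acid would match the ester pattern by
  walking the C–O single bond back to the carbonyl carbon).
* **Unique names.** `t1 != t2` holds iff the ground terms differ
  syntactically. Skolem function symbols are private to one molecule
  predicate, so different molecules never share terms and cardinality
  rules (`atLeastN`) count real atoms.
* **V2000 only.** V3000 tables are rejected; aromatic bond codes are
  rejected rather than kekulized (the bond vocabulary is exactly
  single/double/triple), so input must be kekulized. `M  CHG` property
  lines supersede atom-block charge codes. Disconnected molfiles are
  accepted; all components hang off the single molecule node.

## Evaluation engine

Predicates are partitioned into strata (negative dependencies point
strictly downward; a negative cycle is reported as non-stratified), and
each stratum is evaluated by seminaive fixpoint iteration. Join plans are
greedy (most-bound atom next, then smallest relation), facts are indexed
by predicate and first argument, inequalities and negated atoms are
checked as soon as their variables are bound, and variables that no longer
occur in the remaining body or head are projected away — this keeps
cardinality-style rules (three independent `hasAtom` successors) linear
rather than cubic where possible. The result is a set, and the fixpoint is
order-independent: permuting rule or fact iteration yields the same model.

**Termination.** Existential heads can in principle generate terms
forever. `check_termination` runs a positive chase from a *critical
instance* — one fresh constant seeded into every program predicate, with
negation and inequalities dropped, both of which only add derivations —
and fails as soon as a created skolem term nests its own function symbol.
Passing is sound: the chase over-approximates every concrete run, and with
no symbol repetition the nesting depth is bounded by the number of
function symbols, so evaluation terminates. The check is conservative: it
may reject programs that terminate for subtler reasons. A depth guard
(default 64) backs the engine when the check is explicitly skipped, and a
fact budget (2,000,000) bounds the chase itself. For all packaged
molecule-plus-class programs the check passes and every skolem term has
nesting depth exactly 1.

**Oracle.** `enumerate_stable_models_bruteforce` implements the general
stable-model semantics by guess-and-check over all subsets of the Herbrand
base (Gelfond–Lifschitz reduct, least model, fixpoint test). It is capped
at 16 atoms and exists purely as an independent test oracle for the
engine; the engine itself supports exactly the stratified fragment, which
is all the chemical KBs need.

## Cyclicity

`cyclic` is not expressible in surface syntax and is defined directly as
six rules using edge-avoiding reachability: `reach(u, v, y)` holds when
`y` is reachable from `u` along bond edges without traversing the
undirected bond `{u, v}`; a molecule is cyclic iff some bond can be closed
into a ring (`hasAtom(x, u) ∧ bond(u, v) ∧ reach(u, v, v)`). The "do not
traverse `{u, v}`" condition is spelled out as four inequality-guarded
step rules (the conjunctive normal form of "the step `y → z` is not
`u → v` or `v → u`"). Fixing the reachability source to `u` keeps the
derived relation at arity 3 and quadratic in the bond count per molecule.
This detects rings of arbitrary length and is, by design, part of the
reasoning itself; an optional `fast_cyclic` mode instead computes ring
membership graph-theoretically (networkx) and injects `cyclic` facts —
off by default, provided for large batches.

## Class registry

All class definitions except `cyclic` are single-sourced from surface
axioms and lowered at import. The four groups: existence of subcomponents
(carbonEntity, polyatomicEntity, heteroOrganicEntity, carboxylicAcid with
the middleOxygen helper, carboxylicEster), exact cardinality
(exactly2Carbons via atLeast2/3Carbons), exclusive composition (inorganic,
hydroCarbon via notHydroCarbon, unsaturated, saturated), and cyclicity
(cyclic, alkane). `inorganic` follows the ChEBI definition (no carbon
atoms); exceptions are the modeller's responsibility via extra rules.
Selections close over prerequisites and always include the seven
background rules (single/double/triple ⊑ bond, positive/negative ⊑
charged, h/c ⊑ horc). Default reporting covers molecule-level class
predicates; atom-level helpers (middleOxygen) and the internal `reach`
relation are hidden unless requested. A data file of further ChEBI-style
stubs (halogens, ketone, amine, ...) is shipped as explicitly synthetic,
unvalidated reconstructions outside the core registry.

## Pipeline and partitioning

Classification proceeds in six stages: molfile parsing, KB compilation,
termination check, model computation, optional model storage, subsumption
extraction to CSV. Molecule batches are evaluated in *modules*: each
module contains the class rules plus the structure rules and seed facts of
its own molecules. Because molecules interact only through private skolem
terms, the merged result equals the unpartitioned run for every module
size (tested). Defaults are 20 molecules per module when cyclicity rules
are selected and 50 otherwise — the sizes with the shortest end-to-end
times for the two modes. A failed termination check aborts the pipeline
before any model computation.

## Synthetic data

The fixture generator emulates small organic compounds: 1–10 heavy atoms
from a carbon-rich C/O/N alphabet, connected, valence-capped (C ≤ 4,
O ≤ 2, N ≤ 3, H ≤ 1, counting bond orders), with optional 3–6-carbon
rings (built first, so `ring_probability` 1 and 0 are guarantees, not
expectations), occasional C=C/C=O double bonds, −1 charges on terminal
oxygens, and a few explicit hydrogens (sometimes stereo-flagged so
suppression keeps them). Ground truth (cyclicity, carbon count, element
multiset, carboxy presence per the recognition semantics above,
saturation, hydrocarbon/inorganic/polyatomic flags) is computed by direct
graph algorithms on the generator's own structures, never by the engine.
What generated molecules do *not* emulate: realistic stereochemistry,
aromatic systems (everything is kekulized by construction), isotopes,
multi-fragment records, and the size distribution of curated databases —
so passing tests demonstrate correctness of the logic on valence-plausible
connection tables, not chemical realism of the fixtures.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: the 13-atom reference molecule for the exact worked example, 60
to 200 generated molecules for engine-versus-ground-truth properties, 50
random ground programs against the brute-force oracle, and a 100-molecule
batch under all classes including cyclicity for throughput sanity. There
is no floating-point numerics anywhere: all comparisons are exact set
(in)equalities. Tie-breaking is by canonical string ordering throughout
(sorted fact dumps, sorted rule rendering), which makes compiled KBs and
model files byte-reproducible.

## Known limitations

* Only the stratified fragment is evaluated; disjunctive heads (needed
  e.g. for tautomer mobility) and strong negation are out of scope.
* Aromatic perception, isotopes, 3-D geometry and stereochemistry beyond
  "keep the hydrogen" are not modelled.
* The termination check is conservative and can reject exotic programs
  that do terminate.
* Class-to-class subsumption (a full class hierarchy) is not computed;
  output is molecule-to-class only.
* The pure-Python engine targets correctness and desk-scale batches, not
  the throughput of an optimized deductive database.
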