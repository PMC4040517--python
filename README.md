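# chemrules

Structure-based classification of molecules with nonmonotonic existential
rules.

Curated chemical ontologies such as ChEBI organise molecules under classes
like *carboxylic ester*, *hydrocarbon*, *inorganic molecular entity* or
*cyclic compound*. Many of these classes cannot be captured in OWL-style
description logics: they hinge on the **absence** of features (no carbon
atoms, no carbon–carbon multiple bond) or on **cyclic** structure of
arbitrary size. `chemrules` implements a rule-based alternative for
curators and cheminformaticians: molecular connection tables become logic
programs, class definitions become rules with negation as failure, and
membership is decided by automated reasoning rather than hand-written
detection code.

## The model

A molecule's MDL molfile is abstracted into a *description graph*: atom
nodes labeled with elements (and charges), bond edges labeled
single/double/triple, and a root molecule node linked to every atom by
`hasAtom`. Hydrogens are implicit — suppressed unless their bond carries a
stereo annotation. The graph is unfolded into an existential rule; for
ascorbic acid (nodes 1–6 oxygen, 7–12 carbon, 13 an explicitly kept
hydrogen):

```
ascorbicAcid(x) → molecule(x) ∧ ⋀ᵢ₌₁¹³ hasAtom(x, fᵢ(x))
                ∧ ⋀ᵢ₌₁⁶ o(fᵢ(x)) ∧ ⋀ᵢ₌₇¹² c(fᵢ(x)) ∧ h(f₁₃(x))
                ∧ single(f₇(x), f₁(x)) ∧ ... ∧ double(f₈(x), f₉(x))
```

where each skolem term `fᵢ(x)` stands for atom node *i*. Classes are rules
over this vocabulary, e.g.

```
molecule(x) ∧ not unsaturated(x) → saturated(x)
saturated(x) ∧ hydroCarbon(x) ∧ not cyclic(x) → alkane(x)
```

Seeding the program with a fact `ascorbicAcid(a)` and computing its unique
**stable model** (the programs are stratified) materialises every class
membership; a class subsumes the molecule iff its atom over `a` appears in
the model. A chase-based acyclicity check guarantees beforehand that
skolem-term creation terminates. Class definitions can be written in a
logic-free *surface syntax* (`alkane SuperClassOf saturated AND
hydroCarbon AND NOT cyclic`) that lowers mechanically to rules.

## Worked example

```python
from chemrules import classify_molecules
from chemrules.reference import ascorbic_acid_molfile

result = classify_molecules([ascorbic_acid_molfile()])
for mol, classes in result.assignments.items():
    print(mol)
    for c in classes:
        print(" ", c)
```

prints

```
ascorbic_acid
  atLeast2Carbons
  atLeast3Carbons
  carbonEntity
  carboxylicEster
  cyclic
  heteroOrganicEntity
  notHydroCarbon
  polyatomicEntity
  unsaturated
```

Ascorbic acid is recognised as an unsaturated, polyatomic, heteroorganic,
cyclic, carbon-containing molecule with a carboxylic ester group and at
least three carbons. Just as importantly, `carboxylicAcid` is **absent**:
the molecule has no free carboxy group (its single-bonded ring oxygen is a
*middle* oxygen), and `saturated`, `hydroCarbon`, `inorganic` and `alkane`
are all correctly ruled out by negation as failure.

The same pipeline is available from the shell:

```
chemrules classify --in molecules.sdf --classes all --module-size 20 --out subs.csv
chemrules fixtures --seed 42 --n 100 --out fixtures/
```

`classify` accepts a molfile, an SDF or a directory, partitions molecules
into evaluation modules, runs the termination check, computes the stable
model per module and writes sorted `molecule_id,class_name` pairs.
`fixtures` generates seeded synthetic molecules with an independently
computed ground-truth table.

## Layout

```
src/chemrules/
  chem_io.py      molfile/SDF parsing, hydrogen suppression, description graphs
  logic.py        terms, atoms, rules, programs; safety; the rule dialect
  translation.py  DG → structure rules; background chemical knowledge
  surface.py      surface-syntax parser and lowering to rules
  classes.py      built-in class registry (incl. the cyclicity encoding)
  engine.py       stratification, stable models, termination check, oracle
  pipeline.py     the six-stage classification pipeline
  fixtures.py     synthetic molecule generator with ground truth
  cli.py          `chemrules` command-line interface
docs/             methods note, rule-dialect and surface-syntax grammars
```

See `docs/methods.md` for modelling assumptions, the evaluation engine,
and known limitations.
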