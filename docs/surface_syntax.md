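# Surface syntax

The surface syntax lets a domain expert define chemical classes without
first-order notation. Keywords are case-sensitive and whitespace-separated;
`#` starts a comment; a new axiom begins at a line whose first token is a
name followed by an axiom keyword (at parenthesis depth zero).

## Grammar

```
axioms     := axiom*
axiom      := NAME kind expr
kind       := "SubClassOf" | "SuperClassOf" | "SuperPropertyOf"
expr       := conj ("OR" conj)*
conj       := unary ("AND" unary)*
unary      := "NOT" unary | primary
primary    := "(" expr ")" | graph | NAME restriction?
restriction:= "SOME" filler | "ONLY" filler | "EXACTLY" INT filler
filler     := NAME | graph | "NOT" filler | "(" expr ")"
graph      := gkind "(" nodes? disjoint? edges ")"
gkind      := "Graph" | "GraphNL"
nodes      := "Nodes" "(" node ("," node)* ")"
node       := INT (NAME | "NOT" NAME)*
disjoint   := "DisjointNodes" "(" INT "," INT ")"
            | "DisjointNodes" "(" pair ("," pair)* ")"
pair       := "(" INT "," INT ")"
edges      := "Edges" "(" (edge ("," edge)*)? ")"
edge       := INT INT NAME
```

`GraphNL` is required (and `Graph` rejected) whenever a node carries a
`NOT`-label or a `DisjointNodes` block is present.

## Lowering to rules

* `C SuperClassOf E` produces recognition rules with head `C(x)`:
  * an `OR` of names → one inclusion rule per disjunct;
  * names → positive body atoms; `NOT name` → negated body atoms;
  * `role SOME name` → `role(x, y) ∧ name(y)` (with a `molecule(x)` domain
    guard when the role is `hasAtom` and no `molecule` conjunct is given);
  * `role SOME Graph(...)` → one `role(x, y_i)` atom per node, unary atoms
    for labels, negated atoms for `NOT`-labels, one binary atom per edge,
    and one inequality per disjoint pair;
  * `role ONLY filler` → a violation predicate `not<C>` derived from a
    `role`-successor outside the filler, negated in the main rule; for a
    purely negative filler a registered `role SOME p ⇔ class` equivalence
    is reused when available (e.g. `hasAtom ONLY ( NOT c )` lowers to
    `not carbonEntity(x)`);
  * `role EXACTLY n f` → `atLeast<n>` and `atLeast<n+1>` counting rules
    (with pairwise inequalities) combined as
    `atLeast_n(x) ∧ not atLeast_{n+1}(x) → C(x)`;
  * axioms whose restrictions use the `bond` role describe an *atom-level*
    class: the root variable is an atom, and all atom variables are bound
    to a common molecule by `hasAtom` guards (as in `middleOxygen`).
* `C SubClassOf molecule AND (hasAtom SOME Graph(...))` is a *structure*
  axiom: it unfolds into skolemized rules (one per head conjunct) asserting
  `molecule(x)`, `hasAtom(x, f_i(x))`, node labels and bond-order atoms in
  both directions. `NOT`-labels and disjointness cannot be asserted.
* `P SuperPropertyOf Q1 OR ... OR Qk` → `Q_i(x, y) → P(x, y)`.

Lowering is deterministic and auxiliary predicate names are stable across
runs. Classes not expressible in surface syntax (cyclicity) are added
directly in the rule dialect.
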