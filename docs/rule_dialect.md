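# Rule dialect

Programs (rules plus ground facts) are serialized in a small datalog-like
text dialect. One statement per line (whitespace is otherwise free), `%`
starts a comment running to end of line, every statement ends with `.`.

## Grammar

```
program    := statement*
statement  := fact | rule
fact       := atom "."                      (must be ground)
rule       := atom ":-" body "."            (head first)
            | body "->" atom "."            (body first)
body       := literal ("," literal)*
literal    := "not" atom                    (negation as failure)
            | term "!=" term                (inequality)
            | atom
atom       := PRED "(" term ("," term)* ")" (arity 1..4)
term       := VARIABLE | CONSTANT | fterm
fterm      := "f" INT "@" PRED "(" term ")" (skolem/functional term)
```

Tokens:

* `VARIABLE` — identifier starting with an upper-case letter (`X`, `Y1`);
* `PRED`, `CONSTANT` — identifier starting with a lower-case letter
  (`molecule`, `hasAtom`, `a`);
* `f3@ascorbicAcid(X)` — the functional term standing for atom node 3 of
  the molecule predicate `ascorbicAcid`. Function symbols are private to
  one molecule predicate, so ground functional terms of different molecules
  are never equal.

## Semantics and restrictions

* Safety: every variable in the head, in a negated atom or in an
  inequality must occur in a positive non-inequality body atom.
* Negated atoms must be function-free.
* `t1 != t2` holds iff the two ground terms are syntactically distinct
  (unique name assumption over constants and skolem terms).
* Functional terms may introduce fresh individuals only in rule heads.

`format_rules` renders a program deterministically (facts first, then
rules, each with sorted bodies, all lines sorted), so compiled knowledge
bases are byte-reproducible; `parse_rules ∘ format_rules` is the identity
up to atom ordering.

## Example

```
% background knowledge
bond(X, Y) :- single(X, Y).
horc(X) :- c(X).

% a class definition with negation and an inequality
polyatomicEntity(X) :- molecule(X), hasAtom(X, Y1), hasAtom(X, Y2), Y1 != Y2.
saturated(X) :- molecule(X), not unsaturated(X).

% a structure-rule conjunct and a seed fact
hasAtom(X, f1@water(X)) :- water(X).
water(m0).
```
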