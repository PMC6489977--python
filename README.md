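# fdminer

`fdminer` discovers **minimal functional dependencies**, **equivalent
attribute sets** and **candidate keys** in tabular datasets. It was built
with clinical and demographic record tables in mind — long, narrow extracts
from electronic health record systems whose schemas need profiling before
they can be decomposed, normalized or cleansed — but it works on any
delimited text table whose values only need to be compared for equality.

## The problem and the algorithm

A functional dependency (FD) `X → Y` over a relation `r(U)` states that any
two tuples agreeing on the attribute set `X` also agree on `Y`. Only
*minimal* FDs matter (no proper subset of `X` already determines `Y`);
everything else follows from Armstrong's axioms. Two sets with `X → Y` and
`Y → X` are *equivalent* (`X ↔ Y`), and a minimal `X` whose closure
`X⁺` reaches all of `U` is a *candidate key*.

The search space is the power-set lattice of `U`: `2ⁿ − 1` non-empty
subsets and `n·2ⁿ⁻¹ − n` edges, so column count — not row count — dominates
the cost. `fdminer` walks this lattice level-wise:

1. **Validation by partition cardinality.** `X → A` holds iff
   `card(π_X) = card(π_{XA})`, where `π_X` partitions the rows by their
   projection on `X`. Two group counts replace a quadratic scan over row
   pairs, which is what makes the approach effective on tables with
   hundreds of thousands of rows.
2. **Right-hand-side restriction.** Each candidate `X` is only tested
   against `U \ (X ∪ X*)`, where `X*` is the nontrivial closure accumulated
   so far — anything inside is already implied.
3. **Equivalence detection.** After a level is validated, `Y ⊆ X⁺` and
   `X ⊆ Y⁺` establish `X ↔ Y`; the earlier-generated side is deleted and
   its supersets never get built (Armstrong's axioms guarantee every FD
   through the deleted side can be rewritten through the kept one).
4. **Corrected candidate generation.** The next level contains exactly the
   `(k+1)`-sets *all* of whose `k`-subsets survived. This is the stricter,
   TANE-style Apriori rule; the laxer pairwise-union rule admits candidates
   such as `ABCD` after `ABC` was pruned and then emits non-minimal FDs
   like `ABCD → E`.
5. **Pruning between levels** — four rules: supersets of equivalence-deleted
   candidates go (rule 1); candidates inside a proper subset's closure go
   (rule 2); every candidate inherits the union of its subsets' closures,
   including pruned subsets', so no closure information is lost (rule 3);
   candidates whose propagated closure already covers `U` are superkeys and
   go (rule 4).

Candidate keys are then inferred from the discovered FD set alone: an
Armstrong-closure engine reduces it to a minimum coverage, seeds the key
search with the attributes appearing on no right-hand side (they can never
be derived, so they sit in every key), and expands breadth-first with
superset pruning until every minimal `X` with `X⁺ = U` is found.

## Worked example

The built-in 7-row, 5-attribute demo table:

| A | B | C | D | E |
|---|---|---|---|---|
| 0 | 0 | 0 | 2 | 0 |
| 0 | 1 | 0 | 2 | 0 |
| 0 | 2 | 0 | 2 | 2 |
| 0 | 3 | 1 | 2 | 0 |
| 4 | 1 | 1 | 1 | 4 |
| 4 | 3 | 1 | 1 | 2 |
| 0 | 0 | 1 | 2 | 0 |

```console
$ python examples/discover_example.py
relation: 7 rows x 5 attributes

minimal functional dependencies (rows agreeing on the left side always agree on the right):
  {A} -> {D}
  {B, D} -> {E}
  {B, E} -> {A}
  {B, E} -> {D}
  {C, E} -> {A}
  {C, E} -> {D}
  {D} -> {A}

equivalent attribute sets (each side determines the other):
  {A} <-> {D}
  {B, D} <-> {B, E}

candidate keys (minimal sets that uniquely identify every row):
  {A, B, C}
  {B, C, D}
  {B, C, E}

11 candidate attribute sets were examined out of the 31 non-empty subsets: the pruning rules inferred the rest from Armstrong's axioms.
```

Reading the output: columns `A` and `D` carry the same information (each
determines the other), `{B, D}` and `{B, E}` are an equivalent pair at
level 2, and any of the three keys uniquely identifies a row. Only 11 of
the 31 non-empty attribute subsets were ever validated — equivalence,
redundancy and key pruning inferred the rest.

The same run is available from the shell; it prints the report and saves
it next to your data as `<dataset>.FD_Info.txt`:

```console
$ fdminer path/to/table.csv
$ fdminer path/to/table.csv --time-limit 3600 --separator '|' --output-dir out/
```

Separators (`,` `|` `;` `:` `~`) are auto-detected. Runs that hit the time
limit (default 4 hours) exit with a distinct status and write a partial
report flagged `TRUNCATED`.

Other entry points: `examples/planted_recovery.py` (synthetic data with
planted structure, recovered by discovery), `examples/key_inference.py`
(closures / minimum coverage / keys from a hand-written FD set) and
`examples/search_space.py` (lattice arithmetic and the effect of pruning).

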