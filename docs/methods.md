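# Methods

## Model

A relation `r(U)` is a finite set of attributes `U = {v₁, …, vₘ}` with
tuples of opaque value tokens. An FD `X → Y` is satisfied when every pair
of tuples agreeing on `X` agrees on `Y`; it is minimal when no proper
subset of `X` determines `Y`. All reasoning is equality-based: values are
strings, `"0" ≠ "0.0"`, and no numeric or temporal interpretation is ever
applied. Empty cells are normalized to a single reserved token that equals
itself, keeping the theory two-valued; SQL-style null semantics would break
the cardinality criterion below (a null unequal to itself would split
partition groups that the pairwise definition merges).

FDs are stored with single-attribute right-hand sides (the Decomposition
axiom makes this lossless); the report renders them one per line rather
than merging right-hand sides, so the text form round-trips exactly.

## Validation: partition cardinality

`π_X` groups row indices by equal projection on `X`; `card(π_X)` is its
group count. `X → A` holds iff `card(π_X) = card(π_{XA})` — the grouping by
`X` is already as fine as the grouping by `XA`. The implementation hashes
projection tuples into plain (non-stripped) partitions; cardinalities for
the current and the next lattice level are memoized and entries below the
current level are evicted, matching the level-wise access pattern. The
equivalence of the cardinality criterion with the pairwise definition is
exercised by a dedicated property test against an independent double-loop
checker.

## Level-wise search

Level 1 holds the singletons in lexicographic attribute order; that order
is also the candidate generation order, which matters because equivalence
handling needs a well-defined "generated before". For each candidate `X`
(counted once in `candidates_checked`) the right-hand-side pool is
`U \ (X ∪ X*)` with `X*` the nontrivial closure `X⁺ \ X`; each validated
`X → A` adds `A` to `X*`.

After a level is validated, same-level pairs with `Y ⊆ X ∪ X*` and
`X ⊆ Y ∪ Y*` are recorded as equivalences and the earlier-generated
(lexicographically smaller) side is marked deleted. Deleted candidates
remain available to candidate generation — their supersets are instead
removed by pruning rule 1 — because under the strict generation rule a
candidate removed *before* generation would silently suppress its
supersets and leave rule 1 unreachable.

Generation uses the strict Apriori rule (every `k`-subset must have
survived), implemented as the classic sorted prefix join plus a subset
check. Pruning then applies, for each new candidate `S` and each
one-smaller subset `X ⊂ S`:

1. delete `S` if `X` is the deleted side of an equivalence;
2. delete `S` if `S ⊆ X ∪ X*`;
3. propagate `S* := S* ∪ (X* \ S)` — this runs even for deleted `S`, so
   closure information survives pruning and descendants can inherit it;
4. delete `S` if `S ∪ S* = U` after propagation (`S` is a superkey whose
   FDs are already implied).

Rule 4 is deliberately not applied to the full set `U` itself: `U` is only
trivially a superkey, carries an empty right-hand-side pool, and is still
examined and counted. On a 4-attribute relation with no nontrivial FDs the
search therefore examines 4 + 6 + 4 + 1 = 15 candidates, which is the
reference behavior the counter is tested against. The counter counts
candidates examined, not individual cardinality comparisons.

Termination: at most `|U|` levels, or the wall-clock limit (default
14,400 s, checked between candidates). On expiry the partial result is
returned with `truncated=True` and the CLI exits with a distinct status.

## Key inference

Candidate keys are computed from the discovered FD set (equivalence pairs
expanded into both FD directions) rather than read off the lattice —
key pruning removes superkey candidates before they are validated, but by
construction rule 4 only fires when the recorded FDs already imply the
superkey, so nothing is lost.

The engine: Armstrong closure as a least fixpoint; minimum coverage by
removing extraneous left-hand attributes and then redundant FDs, in
canonical order for determinism (the result is an irreducible equivalent
set, not necessarily unique in general — canonical ordering pins one);
key search seeded with the core (attributes on no right-hand side of the
coverage), expanded breadth-first over the attributes that are neither in
the core nor derivable from it — adding a derivable attribute can never
yield a minimal key — with supersets of found keys skipped. The worst-case
key count is exponential; a configurable cap (default 10,000) aborts
pathological inputs with a clear error instead of exhausting memory.

Key inference presumes the relation is duplicate-row-free, as FD-based
reasoning cannot observe row duplication; the exhaustive key oracle returns
the empty set on tables with duplicate rows, and the two are only compared
on duplicate-free inputs.

## Input handling

Separator detection samples the first 20 non-empty lines (bounded cost,
robust to long files) and accepts the first of `,` `|` `;` `:` `~` — in
that precedence order — that splits every sampled line into the same field
count greater than one. No qualifying candidate means a single-column
file, unless a candidate character appears in the header, which signals a
ragged file and raises a parse error. With a known separator, ragged rows
are reported with their line number. The pickled-DataFrame input is
feature-gated behind an explicit flag; delimited text is canonical.

## Synthetic data

The generator emulates dependency structure only: free columns draw
uniformly from a pool of 8 distinct values by default (a realistic
cardinality for coded clinical fields such as visit types or lab panels);
planted FDs compute the right-hand column as a seeded deterministic
function of the left-hand projection; planted equivalences are bijections
between two columns. The planted-rule graph must be acyclic and no column
may be the target of two rules. It does not emulate value distributions,
missingness patterns, or cross-column correlations of real record tables,
so passing tests certify the discovery logic, not robustness to real-data
quirks.

The FD-free generator rejection-samples independent columns until the
brute-force oracle certifies the absence of nontrivial FDs (guard: at
least 4 rows per pool value, at most 100 rounds). The oracle itself is a
literal double loop over row pairs with early exit — intentionally naive
and partition-free, so it is an independent check on the search, and
guarded to at most 10 attributes.

## Problem sizes in the test suite

Desk-scale sizes keep every property exhaustively checkable: the oracle
sweep uses 200 randomized relations with 2–6 attributes, 10–200 rows and
2–6 distinct values per column, half of them with planted FDs or
equivalences; the counter check uses 500 rows × 4 attributes; closure
comparisons enumerate all attribute subsets. These sizes make brute-force
verification of every emitted FD and key feasible while exercising every
pruning rule.

## Known limitations

- Exact FDs only: no approximate, partial or conditional dependencies, no
  error thresholds.
- Lattice traversal is memory-hungry on wide tables; beyond roughly 14
  attributes the level sizes explode and a different algorithm family
  (dependency induction) is the better tool.
- No schema decomposition (3NF/BCNF) — discovery output is the input such
  a step would take.
- Report timing excludes file reading, so it measures discovery cost only.
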