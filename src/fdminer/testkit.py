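"""Brute-force oracles and synthetic relations with planted structure.

The oracles decide FDs straight from the pairwise definition — a literal
double loop over row pairs with early exit on a violating pair — and share
no code with the partition machinery, so they can stand as an independent
cross-check of the lattice search.  They are guarded to small attribute
counts; desk-scale verification is their only job.

The generator plants dependency structure (FDs as deterministic functions
of the left-hand projection, equivalences as bijections between columns)
into otherwise independent random columns.  It emulates only the
dependency structure of record tables, not value distributions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .errors import GenerationError, SyntheticSpecError
from .fdmine import FunctionalDependency
from .keyinfer import FDSet
from .lattice import AttributeSet, attribute_set
from .partition import fd_holds
from .relation_io import Relation

_MAX_ORACLE_ATTRIBUTES = 10

#: Default number of distinct values a free column draws from.
DEFAULT_DISTINCT_VALUES = 8

# 7x5 worked-example table: A and D are equivalent single attributes and
# the candidate keys are {A,B,C}, {B,C,D} and {B,C,E}.
_EXAMPLE_ATTRIBUTES = ("A", "B", "C", "D", "E")
_EXAMPLE_ROWS = (
    ("0", "0", "0", "2", "0"),
    ("0", "1", "0", "2", "0"),
    ("0", "2", "0", "2", "2"),
    ("0", "3", "1", "2", "0"),
    ("4", "1", "1", "1", "4"),
    ("4", "3", "1", "1", "2"),
    ("0", "0", "1", "2", "0"),
)


def example_relation() -> Relation:
    """The small worked-example relation used throughout the docs."""
    return Relation(name="example", attributes=_EXAMPLE_ATTRIBUTES, rows=_EXAMPLE_ROWS)


def _pairwise_satisfies(
    rows: Sequence[tuple[str, ...]], lhs_idx: Sequence[int], rhs_idx: int
) -> bool:
    """Definition check: rows agreeing on lhs must agree on rhs."""
    proj = [tuple(r[i] for i in lhs_idx) for r in rows]
    n = len(rows)
    for i in range(n):
        pi, ri = proj[i], rows[i][rhs_idx]
        for j in range(i + 1, n):
            if proj[j] == pi and rows[j][rhs_idx] != ri:
                return False
    return True


def _guard(relation: Relation) -> None:
    if len(relation.attributes) > _MAX_ORACLE_ATTRIBUTES:
        raise SchemaGuardError(len(relation.attributes))


class SchemaGuardError(ValueError):
    def __init__(self, n: int) -> None:
        super().__init__(
            f"oracle is limited to {_MAX_ORACLE_ATTRIBUTES} attributes, got {n}"
        )


def brute_force_minimal_fds(relation: Relation) -> FDSet:
    """All minimal FDs of a relation, by exhaustive subset enumeration.

    For each right-hand attribute the left-hand subsets are scanned in
    increasing size; a subset is skipped once any recorded smaller
    left-hand side for the same attribute is contained in it.
    """
    _guard(relation)
    attrs = attribute_set(relation.attributes)
    index = {a: i for i, a in enumerate(relation.attributes)}
    fds: list[FunctionalDependency] = []
    for rhs in attrs:
        others = [a for a in attrs if a != rhs]
        minimal: list[tuple[str, ...]] = []
        for size in range(1, len(others) + 1):
            for lhs in combinations(others, size):
                if any(set(m) <= set(lhs) for m in minimal):
                    continue
                if _pairwise_satisfies(
                    relation.rows, [index[a] for a in lhs], index[rhs]
                ):
                    minimal.append(lhs)
                    fds.append(FunctionalDependency(lhs, rhs))
    return FDSet(universe=attrs, fds=tuple(sorted(fds)))


def brute_force_keys(relation: Relation) -> tuple[AttributeSet, ...]:
    """All minimal attribute sets that uniquely identify every row.

    Empty when the relation contains duplicate full rows — no attribute
    set can separate identical tuples.
    """
    _guard(relation)
    attrs = attribute_set(relation.attributes)
    n = relation.n_rows
    index = {a: i for i, a in enumerate(relation.attributes)}
    keys: list[AttributeSet] = []
    for size in range(1, len(attrs) + 1):
        for cand in combinations(attrs, size):
            if any(set(k) <= set(cand) for k in keys):
                continue
            idx = [index[a] for a in cand]
            if len({tuple(r[i] for i in idx) for r in relation.rows}) == n:
                keys.append(cand)
    return tuple(sorted(keys))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic relation with planted dependency structure.

    ``planted_fds`` right-hand sides are computed as seeded deterministic
    functions of the left-hand projection; ``planted_equivalences`` are
    (source, mirror) single-attribute pairs planted as bijections.  The
    dependency graph of planted rules must be acyclic and no attribute may
    be the target of two rules.
    """

    n_rows: int
    attributes: tuple[str, ...]
    planted_fds: tuple[FunctionalDependency, ...] = ()
    planted_equivalences: tuple[tuple[str, str], ...] = ()
    distinct_values_per_free_attribute: int = DEFAULT_DISTINCT_VALUES
    seed: int = 0

    def derived_targets(self) -> dict[str, tuple[str, ...]]:
        """Map each derived attribute to the attributes it is computed from."""
        targets: dict[str, tuple[str, ...]] = {}
        for fd in self.planted_fds:
            if fd.rhs in targets:
                raise SyntheticSpecError(
                    f"attribute {fd.rhs!r} is the target of two planted rules"
                )
            targets[fd.rhs] = tuple(fd.lhs)
        for source, mirror in self.planted_equivalences:
            if mirror in targets:
                raise SyntheticSpecError(
                    f"attribute {mirror!r} is the target of two planted rules"
                )
            targets[mirror] = (source,)
        return targets


def _validate_spec(spec: SyntheticSpec) -> dict[str, tuple[str, ...]]:
    declared = set(spec.attributes)
    if len(declared) != len(spec.attributes):
        raise SyntheticSpecError("duplicate attribute names")
    for fd in spec.planted_fds:
        if not set(fd.lhs) <= declared or fd.rhs not in declared:
            raise SyntheticSpecError(f"planted FD {fd} references undeclared attributes")
    for source, mirror in spec.planted_equivalences:
        if source not in declared or mirror not in declared:
            raise SyntheticSpecError(
                f"planted equivalence ({source}, {mirror}) references "
                "undeclared attributes"
            )
    targets = spec.derived_targets()
    # topological order check over the derivation graph
    resolved = declared - set(targets)
    pending = dict(targets)
    while pending:
        ready = [a for a, deps in pending.items() if set(deps) <= resolved]
        if not ready:
            raise SyntheticSpecError(
                f"planted rules form a cycle through {sorted(pending)}"
            )
        for a in ready:
            resolved.add(a)
            del pending[a]
    return targets


def generate_relation(spec: SyntheticSpec) -> Relation:
    """Build a relation realizing a synthetic specification.

    Free attributes draw uniformly from their value pool; every planted FD
    and equivalence verifiably holds on the output (checked with the
    cardinality criterion before returning).  The same spec and seed yield
    an identical relation.
    """
    targets = _validate_spec(spec)
    if spec.n_rows < 0:
        raise SyntheticSpecError("n_rows must be non-negative")
    rng = random.Random(spec.seed)
    pool = [str(v) for v in range(spec.distinct_values_per_free_attribute)]
    columns: dict[str, list[str]] = {}
    for a in spec.attributes:  # free columns first, in declaration order
        if a not in targets:
            columns[a] = [rng.choice(pool) for _ in range(spec.n_rows)]
    pending = dict(targets)
    equivalence_mirrors = {mirror for _, mirror in spec.planted_equivalences}
    while pending:
        for a in sorted(pending):
            deps = pending[a]
            if not all(d in columns for d in deps):
                continue
            if a in equivalence_mirrors:
                bijection = dict(zip(pool, rng.sample(pool, len(pool))))
                columns[a] = [bijection[v] for v in columns[deps[0]]]
            else:
                mapping: dict[tuple[str, ...], str] = {}
                values = []
                for i in range(spec.n_rows):
                    key = tuple(columns[d][i] for d in deps)
                    if key not in mapping:
                        mapping[key] = rng.choice(pool)
                    values.append(mapping[key])
                columns[a] = values
            del pending[a]
            break
    rows = tuple(
        tuple(columns[a][i] for a in spec.attributes) for i in range(spec.n_rows)
    )
    relation = Relation(
        name=f"synthetic-{spec.seed}", attributes=spec.attributes, rows=rows
    )
    for fd in spec.planted_fds:
        if not fd_holds(relation, fd.lhs, fd.rhs):
            raise GenerationError(f"planted FD {fd} does not hold")
    for source, mirror in spec.planted_equivalences:
        if not (
            fd_holds(relation, (source,), mirror)
            and fd_holds(relation, (mirror,), source)
        ):
            raise GenerationError(
                f"planted equivalence ({source}, {mirror}) does not hold"
            )
    return relation


def generate_fd_free_relation(
    n_rows: int,
    attributes: Sequence[str],
    seed: int,
    distinct_values: int = DEFAULT_DISTINCT_VALUES,
    max_rounds: int = 100,
) -> Relation:
    """A relation of independent random columns with no nontrivial FD.

    Samples independent columns and rejects until the brute-force oracle
    reports an empty minimal-FD set.  Requires enough rows relative to the
    value pools (at least four times the pool size) so that accidental FDs
    stay improbable and the rejection loop terminates quickly.
    """
    attributes = tuple(attributes)
    if n_rows < 4 * distinct_values:
        raise GenerationError(
            f"need n_rows >= {4 * distinct_values} for pools of "
            f"{distinct_values} values, got {n_rows}"
        )
    for round_index in range(max_rounds):
        child_seed = (seed * 1_000_003 + round_index) % (2**31)
        candidate = generate_relation(
            SyntheticSpec(
                n_rows=n_rows,
                attributes=attributes,
                distinct_values_per_free_attribute=distinct_values,
                seed=child_seed,
            )
        )
        if not brute_force_minimal_fds(candidate).fds:
            return candidate
    raise GenerationError(
        f"no FD-free relation found in {max_rounds} resampling rounds"
    )
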