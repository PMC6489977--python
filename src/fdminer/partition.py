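"""Row partitions and cardinality-based validation of functional dependencies.

The partition of a relation over an attribute set X groups together the
rows whose projections on X are equal.  An FD X -> Y holds exactly when
grouping by X already separates the rows as finely as grouping by X and Y
together, i.e. ``card(pi_X) == card(pi_XY)``.  This turns FD validation
into two group counts instead of a quadratic scan over row pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import SchemaError
from .relation_io import Relation


@dataclass(frozen=True)
class Partition:
    """Grouping of row indices by equal projection on ``source``.

    Groups are pairwise disjoint, jointly cover all row indices (0-based),
    and are ordered by their first row index.  ``cardinality`` is the
    number of groups.
    """

    source: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]

    @property
    def cardinality(self) -> int:
        return len(self.groups)


def _column_indices(relation: Relation, attrs: Iterable[str]) -> list[int]:
    positions = {a: i for i, a in enumerate(relation.attributes)}
    try:
        return [positions[a] for a in attrs]
    except KeyError as exc:
        raise SchemaError(f"unknown attribute {exc.args[0]!r}") from None


def compute_partition(relation: Relation, attrs: Sequence[str]) -> Partition:
    """Group row indices of ``relation`` by equal projection on ``attrs``.

    ``attrs`` must be a non-empty subset of the schema.  Group order is
    deterministic: groups appear in order of their first row index.
    """
    if not attrs:
        raise SchemaError("attribute set must be non-empty")
    idx = _column_indices(relation, attrs)
    groups: dict[tuple[str, ...], list[int]] = {}
    for row_index, row in enumerate(relation.rows):
        groups.setdefault(tuple(row[i] for i in idx), []).append(row_index)
    return Partition(
        source=tuple(attrs),
        groups=tuple(tuple(g) for g in groups.values()),
    )


def cardinality(partition: Partition) -> int:
    """Number of groups in the partition (distinct projections)."""
    return partition.cardinality


def projection_cardinality(relation: Relation, attrs: Sequence[str]) -> int:
    """``card(pi_attrs)`` without materializing the groups."""
    if not attrs:
        raise SchemaError("attribute set must be non-empty")
    idx = _column_indices(relation, attrs)
    return len({tuple(row[i] for i in idx) for row in relation.rows})


def fd_holds(relation: Relation, lhs: Sequence[str], rhs: str) -> bool:
    """Validate the FD ``lhs -> rhs`` by comparing partition cardinalities.

    Returns True iff ``card(pi_lhs) == card(pi_{lhs ∪ {rhs}})``, which is
    equivalent to the pairwise definition: any two rows agreeing on ``lhs``
    also agree on ``rhs``.  Trivial FDs (``rhs in lhs``) always hold.
    """
    if not lhs:
        raise SchemaError("left-hand side must be non-empty")
    _column_indices(relation, [rhs])  # schema check
    if rhs in lhs:
        return True
    return projection_cardinality(relation, lhs) == projection_cardinality(
        relation, tuple(lhs) + (rhs,)
    )


def is_superkey(relation: Relation, attrs: Sequence[str]) -> bool:
    """True iff no two rows agree on ``attrs`` (projection count = row count)."""
    return projection_cardinality(relation, attrs) == relation.n_rows
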