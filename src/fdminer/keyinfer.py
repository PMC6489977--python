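"""Armstrong-closure engine, minimum coverage, and candidate-key search.

Given a set F of single-right-hand-side FDs over a universe U, the closure
X+ of an attribute set X is the least fixpoint of repeatedly adding the
right-hand side of any FD whose left-hand side is already contained.  A
candidate key is a minimal X with X+ = U.  The search seeds from the
mandatory core — attributes appearing on no right-hand side of the minimum
coverage can never be derived, so they sit in every key — and expands
breadth-first, pruning supersets of keys already found.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .errors import KeyExplosionError, SchemaError
from .fdmine import FunctionalDependency
from .lattice import AttributeSet, attribute_set

#: Abort the key search beyond this many keys (worst case is exponential).
DEFAULT_MAX_KEYS = 10_000


@dataclass(frozen=True)
class FDSet:
    """A universe of attributes plus a duplicate-free set of FDs over it."""

    universe: AttributeSet
    fds: tuple[FunctionalDependency, ...]

    def __post_init__(self) -> None:
        members = set(self.universe)
        for fd in self.fds:
            if not set(fd.lhs) <= members or fd.rhs not in members:
                raise SchemaError(f"FD {fd} references attributes outside {self.universe}")
        canonical = tuple(dict.fromkeys(
            FunctionalDependency(attribute_set(fd.lhs), fd.rhs) for fd in self.fds
        ))
        object.__setattr__(self, "fds", canonical)


def armstrong_closure(x: Iterable[str], f: FDSet) -> AttributeSet:
    """X+ with respect to ``f``: the least fixpoint over the FD rules."""
    closed = set(x)
    if not closed <= set(f.universe):
        raise SchemaError(f"{sorted(closed)} is not a subset of the universe")
    changed = True
    while changed:
        changed = False
        for lhs, rhs in f.fds:
            if rhs not in closed and set(lhs) <= closed:
                closed.add(rhs)
                changed = True
    return attribute_set(closed)


def minimum_coverage(f: FDSet) -> FDSet:
    """An equivalent, irreducible FD set.

    No FD can be dropped and no left-hand attribute removed without
    changing some closure.  FDs are processed in canonical order, so the
    result is deterministic.  Closures are preserved: for every X ⊆ U,
    ``armstrong_closure(X, f) == armstrong_closure(X, minimum_coverage(f))``.
    """
    current = sorted(f.fds)
    # drop extraneous left-hand attributes
    reduced = []
    for i, (lhs, rhs) in enumerate(current):
        working = list(lhs)
        for attr in list(lhs):
            if len(working) == 1:
                break
            trial = [a for a in working if a != attr]
            pool = FDSet(f.universe, tuple(reduced + current[i:]))
            if rhs in armstrong_closure(trial, pool):
                working = trial
        reduced.append(FunctionalDependency(attribute_set(working), rhs))
    # drop redundant FDs
    kept = list(dict.fromkeys(reduced))
    for fd in sorted(kept):
        rest = [g for g in kept if g != fd]
        if fd.rhs in armstrong_closure(fd.lhs, FDSet(f.universe, tuple(rest))):
            kept = rest
    return FDSet(f.universe, tuple(sorted(kept)))


def candidate_keys(f: FDSet, max_keys: int = DEFAULT_MAX_KEYS) -> tuple[AttributeSet, ...]:
    """All minimal attribute sets whose closure is the whole universe.

    Seeds from the mandatory core, expands breadth-first by level over the
    attributes that are neither in the core nor derivable from it (adding
    a derivable attribute can never make a set minimal), and prunes
    supersets of keys already found.  Raises :class:`KeyExplosionError`
    past ``max_keys`` keys.
    """
    if not f.universe:
        raise SchemaError("universe must be non-empty")
    cover = minimum_coverage(f)
    rhs_attrs = {fd.rhs for fd in cover.fds}
    core = attribute_set(a for a in f.universe if a not in rhs_attrs)
    base = set(armstrong_closure(core, cover))
    if base == set(f.universe):
        return (core,)
    extras = [a for a in f.universe if a not in core and a not in base]
    keys: list[AttributeSet] = []
    for size in range(1, len(extras) + 1):
        for combo in combinations(extras, size):
            cand = attribute_set(core + combo)
            if any(set(k) <= set(cand) for k in keys):
                continue
            if set(armstrong_closure(cand, cover)) == set(f.universe):
                keys.append(cand)
                if len(keys) > max_keys:
                    raise KeyExplosionError(
                        f"more than {max_keys} candidate keys; raise max_keys "
                        "to continue"
                    )
    return tuple(sorted(keys))
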