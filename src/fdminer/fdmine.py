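"""Level-wise discovery of minimal functional dependencies.

The search walks the power-set lattice bottom-up.  At each level every
surviving candidate X is validated against the attributes not already in
its nontrivial closure X* (anything in X* is derivable from FDs found at
lower levels, so testing it could only produce a non-minimal FD).  After a
level is validated, equivalent attribute sets (X <-> Y, mutual dependence)
are detected from the recorded closures, the next level is generated with
the corrected Apriori rule — all k-subsets must have survived — and four
pruning rules fire between levels:

1. equivalence pruning: supersets of the deleted side of an equivalence
   carry no new information (Armstrong's axioms let every FD through the
   deleted side be rewritten through the kept side);
2. redundancy pruning: a candidate contained in a proper subset's closure
   determines exactly what that subset does;
3. closure propagation: a candidate inherits the union of its proper
   subsets' closures, including those of subsets that were themselves
   pruned, so no closure information is lost;
4. key pruning: a candidate whose propagated closure already covers the
   whole schema is a superkey; its FDs are implied and all its supersets
   are non-minimal.

Candidate keys are not read off the lattice: they are inferred afterwards
from the discovered FD set by the Armstrong-closure engine in
:mod:`fdminer.keyinfer`, which reconstructs exactly the keys the pruned
candidates would have witnessed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .errors import SchemaError
from .lattice import (
    AttributeSet,
    CandidateLevel,
    apriori_gen,
    attribute_set,
    one_down,
)
from .partition import projection_cardinality
from .relation_io import Relation

logger = logging.getLogger(__name__)

#: Default wall-clock budget for a discovery run: four hours.
DEFAULT_TIME_LIMIT_SECONDS = 14_400.0


class FunctionalDependency(NamedTuple):
    """A nontrivial FD with a single right-hand-side attribute."""

    lhs: AttributeSet
    rhs: str

    def __str__(self) -> str:
        return "{%s} -> {%s}" % (", ".join(self.lhs), self.rhs)


@dataclass
class ClosureMap:
    """Persistent registry mapping every generated candidate X to X*.

    X* is the nontrivial closure (X+ minus X itself), so entries are always
    disjoint from their key.  Entries survive pruning: a deleted
    candidate's closure is still propagated to its supersets.
    """

    entries: dict[AttributeSet, set[str]] = field(default_factory=dict)

    def star(self, x: AttributeSet) -> set[str]:
        """The stored X*, created empty on first access."""
        return self.entries.setdefault(x, set())


@dataclass
class EquivalenceRegistry:
    """Unordered equivalence pairs and the candidates they deleted.

    Each recorded pair (X, Y) satisfies X -> Y and Y -> X; the sides are
    incomparable (same-level candidates never contain each other).  The
    earlier-generated — lexicographically smaller — side goes into
    ``deleted`` and its supersets are pruned from later levels.
    """

    pairs: list[tuple[AttributeSet, AttributeSet]] = field(default_factory=list)
    deleted: set[AttributeSet] = field(default_factory=set)


@dataclass
class Counters:
    """Mutable progress counters threaded through the level loop."""

    candidates_checked: int = 0
    fds_found: int = 0
    truncated: bool = False


@dataclass(frozen=True)
class DiscoveryResult:
    """Everything a discovery run produces."""

    fds: tuple[FunctionalDependency, ...]
    equivalences: tuple[tuple[AttributeSet, AttributeSet], ...]
    keys: tuple[AttributeSet, ...]
    candidates_checked: int
    fds_found: int
    rows: int
    attribute_count: int
    elapsed_seconds: float
    truncated: bool


def _cardinality(
    relation: Relation,
    attrs: AttributeSet,
    cache: Optional[dict[AttributeSet, int]],
) -> int:
    if cache is None:
        return projection_cardinality(relation, attrs)
    card = cache.get(attrs)
    if card is None:
        card = projection_cardinality(relation, attrs)
        cache[attrs] = card
    return card


def obtain_fds(
    relation: Relation,
    level: CandidateLevel,
    closures: ClosureMap,
    counters: Counters,
    *,
    cache: Optional[dict[AttributeSet, int]] = None,
    deadline: Optional[float] = None,
) -> list[FunctionalDependency]:
    """Validate one lattice level and return the newly found minimal FDs.

    For each candidate X (counted once in ``candidates_checked``) the
    right-hand-side pool is U \\ (X ∪ X*); each pool attribute A is tested
    with the cardinality criterion and, when X -> A holds, A is added to
    X* and the FD recorded.  Candidates are visited in lexicographic
    order, pool attributes likewise, so counters and logs are
    reproducible.  The optional ``deadline`` (``time.monotonic`` value) is
    checked between candidates; on expiry ``counters.truncated`` is set
    and the partial result returned.
    """
    universe = attribute_set(relation.attributes)
    found: list[FunctionalDependency] = []
    for x in level.candidates:
        if deadline is not None and time.monotonic() >= deadline:
            counters.truncated = True
            break
        counters.candidates_checked += 1
        x_star = closures.star(x)
        pool = [a for a in universe if a not in x and a not in x_star]
        if not pool:
            continue
        card_x = _cardinality(relation, x, cache)
        for a in pool:
            xa = attribute_set(x + (a,))
            if _cardinality(relation, xa, cache) == card_x:
                fd = FunctionalDependency(x, a)
                found.append(fd)
                x_star.add(a)
                logger.debug("validated %s", fd)
    counters.fds_found += len(found)
    return found


def obtain_equivalences(
    level: CandidateLevel,
    closures: ClosureMap,
    registry: EquivalenceRegistry,
) -> EquivalenceRegistry:
    """Detect equivalent attribute sets within a fully validated level.

    Two same-level candidates X, Y (X generated first) are equivalent when
    Y ⊆ X ∪ X* and X ⊆ Y ∪ Y*: each side's closure reaches the other, so
    mutual dependence follows from Armstrong's axioms.  The pair is
    recorded once and the earlier-generated side X is marked for deletion.
    """
    candidates = level.candidates
    for i, x in enumerate(candidates):
        x_plus = set(x) | closures.star(x)
        for y in candidates[i + 1 :]:
            if set(y) <= x_plus and set(x) <= set(y) | closures.star(y):
                registry.pairs.append((x, y))
                registry.deleted.add(x)
                logger.debug("equivalence {%s} <-> {%s}; deleting the former",
                             ", ".join(x), ", ".join(y))
    return registry


def prune(
    next_level: CandidateLevel,
    registry: EquivalenceRegistry,
    closures: ClosureMap,
    universe: AttributeSet,
) -> CandidateLevel:
    """Apply the four pruning rules to a freshly generated level.

    For every candidate S and every proper one-smaller subset X:
    rule 1 deletes S when X is the deleted side of an equivalence;
    rule 2 deletes S when S ⊆ X ∪ X* (S determines nothing beyond X);
    rule 3 propagates S* := S* ∪ (X* \\ S);
    rule 4 deletes S when S ∪ S* = U after propagation (S is a superkey
    whose status is already implied by the recorded FDs).  Rule 4 is not
    applied to the full set U itself, which is only trivially a superkey
    and still gets examined (and counted) by the level loop.

    Closure propagation runs even for deleted candidates so their
    descendants can inherit it.
    """
    universe_set = set(universe)
    kept = []
    for s in next_level.candidates:
        s_set = set(s)
        s_star = closures.star(s)
        deleted = False
        for x in one_down(s):
            x_star = closure_of_subset(x, closures)
            if x in registry.deleted:  # rule 1
                deleted = True
            if s_set <= set(x) | x_star:  # rule 2
                deleted = True
            s_star |= x_star - s_set  # rule 3
        if s != universe and s_set | s_star == universe_set:  # rule 4
            if not deleted:
                logger.debug("superkey pruned: {%s}", ", ".join(s))
            deleted = True
        if not deleted:
            kept.append(s)
    return CandidateLevel(k=next_level.k, candidates=tuple(kept))


def closure_of_subset(x: AttributeSet, closures: ClosureMap) -> set[str]:
    """Resolve X*, falling back to the union of proper-subset closures.

    Candidates deleted before being generated at some level never received
    a stored entry; their closure is reconstructed recursively from the
    one-down subsets (and memoized), so no propagated information is lost.
    Singletons that were never generated close to the empty set.
    """
    stored = closures.entries.get(x)
    if stored is not None:
        return set(stored)
    if len(x) <= 1:
        closures.entries[x] = set()
        return set()
    acc: set[str] = set()
    for sub in one_down(x):
        acc |= closure_of_subset(sub, closures)
    acc -= set(x)
    closures.entries[x] = acc
    return set(acc)


def run_fdmine(
    relation: Relation,
    time_limit_seconds: float = DEFAULT_TIME_LIMIT_SECONDS,
) -> DiscoveryResult:
    """Run the full level-wise discovery on a relation.

    Iterates validate / detect-equivalences / generate / prune until the
    candidate level is empty or the time limit fires (the partial result
    is then returned with ``truncated=True``).  Candidate keys are filled
    in afterwards from the discovered FDs, with every equivalence pair
    expanded into its two FD directions.
    """
    from .keyinfer import FDSet, candidate_keys  # deferred: keyinfer imports FD type

    if not relation.attributes:
        raise SchemaError("relation has no attributes")
    if time_limit_seconds <= 0:
        raise ValueError("time_limit_seconds must be positive")
    start = time.monotonic()
    deadline = start + time_limit_seconds
    universe = attribute_set(relation.attributes)
    closures = ClosureMap()
    registry = EquivalenceRegistry()
    counters = Counters()
    cache: dict[AttributeSet, int] = {}
    fds: list[FunctionalDependency] = []
    level = CandidateLevel(k=1, candidates=tuple((a,) for a in universe))
    while level.candidates:
        fds.extend(
            obtain_fds(
                relation, level, closures, counters, cache=cache, deadline=deadline
            )
        )
        if counters.truncated:
            break
        obtain_equivalences(level, closures, registry)
        level = prune(apriori_gen(level), registry, closures, universe)
        # partitions of sets smaller than the new level are never needed again
        cache = {k: v for k, v in cache.items() if len(k) >= level.k}

    expanded = list(fds)
    for x, y in registry.pairs:
        for a in sorted(set(y) - set(x)):
            expanded.append(FunctionalDependency(x, a))
        for a in sorted(set(x) - set(y)):
            expanded.append(FunctionalDependency(y, a))
    fdset = FDSet(universe=universe, fds=tuple(dict.fromkeys(expanded)))
    keys = candidate_keys(fdset)

    return DiscoveryResult(
        fds=tuple(sorted(fds)),
        equivalences=tuple(registry.pairs),
        keys=tuple(sorted(keys)),
        candidates_checked=counters.candidates_checked,
        fds_found=counters.fds_found,
        rows=relation.n_rows,
        attribute_count=len(relation.attributes),
        elapsed_seconds=time.monotonic() - start,
        truncated=counters.truncated,
    )
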