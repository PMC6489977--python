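"""Candidate bookkeeping on the power-set lattice.

Attribute sets are kept canonical (sorted, duplicate-free tuples), so equal
sets are structurally identical and usable as registry keys.  Candidate
generation is the corrected, TANE-style Apriori rule: a (k+1)-set is
generated only when *all* of its k-subsets survived at level k.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

AttributeSet = tuple[str, ...]


def attribute_set(names: Iterable[str]) -> AttributeSet:
    """Canonical form: lexicographically sorted, duplicate-free tuple."""
    return tuple(sorted(set(names)))


@dataclass(frozen=True)
class CandidateLevel:
    """The set of size-k candidates at one lattice level, in lexicographic order.

    An empty ``candidates`` tuple signals termination of the level-wise
    search.
    """

    k: int
    candidates: tuple[AttributeSet, ...]

    def __post_init__(self) -> None:
        for c in self.candidates:
            if len(c) != self.k:
                raise ValueError(f"candidate {c} is not at level {self.k}")


def one_down(x: AttributeSet) -> tuple[AttributeSet, ...]:
    """All (k-1)-subsets of ``x`` in lexicographic order; empty for singletons."""
    if len(x) <= 1:
        return ()
    return tuple(combinations(x, len(x) - 1))


def apriori_gen(level: CandidateLevel) -> CandidateLevel:
    """Generate level k+1 from the surviving level-k candidates.

    Returns exactly the (k+1)-sets whose every k-subset is in the input
    level, enumerated in lexicographic order of canonical form.  Uses the
    classic prefix join: two lexicographically sorted k-sets sharing their
    first k-1 members join into a (k+1)-set, which is then subset-checked.
    """
    present = set(level.candidates)
    ordered = sorted(present)
    out = []
    for i, p in enumerate(ordered):
        for q in ordered[i + 1 :]:
            if p[:-1] != q[:-1]:
                break
            joined = p + (q[-1],)
            if all(sub in present for sub in one_down(joined)):
                out.append(joined)
    return CandidateLevel(k=level.k + 1, candidates=tuple(sorted(out)))


def lattice_counts(n: int) -> tuple[int, int, int]:
    """Search-space sizes for an n-attribute schema.

    Returns ``(subsets, candidates, edges)``: the 2^n - 1 non-empty
    attribute subsets, the 2^n - 2 proper non-empty subsets considered as
    left-hand-side candidates (U itself trivially determines only its own
    subsets), and the n * 2^(n-1) - n arrows of the semi-lattice, i.e. the
    pairs (X, X ∪ {a}) with X non-empty.
    """
    if n < 1:
        raise ValueError(f"attribute count must be >= 1, got {n}")
    return (2**n - 1, 2**n - 2, n * 2 ** (n - 1) - n)
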