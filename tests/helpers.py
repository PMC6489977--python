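"""Shared helpers for the test suite.

The pairwise FD check and the closure-comparison helpers are deliberately
self-contained (no partition machinery) so they can serve as independent
oracles for the implementation under test.
"""

from functools import lru_cache
from itertools import combinations
import random

from fdminer import FDSet, FunctionalDependency, armstrong_closure
from fdminer.relation_io import Relation


def pairwise_fd_check(relation, lhs, rhs):
    """Direct double-loop implementation of the FD definition."""
    index = {a: i for i, a in enumerate(relation.attributes)}
    lhs_idx = [index[a] for a in lhs]
    rhs_idx = index[rhs]
    for i, ri in enumerate(relation.rows):
        for rj in relation.rows[i + 1 :]:
            if all(ri[k] == rj[k] for k in lhs_idx) and ri[rhs_idx] != rj[rhs_idx]:
                return False
    return True


def expanded_fdset(result, universe):
    """Discovered FDs plus both directions of every recorded equivalence."""
    fds = list(result.fds)
    for x, y in result.equivalences:
        for a in sorted(set(y) - set(x)):
            fds.append(FunctionalDependency(x, a))
        for a in sorted(set(x) - set(y)):
            fds.append(FunctionalDependency(y, a))
    return FDSet(universe=universe, fds=tuple(dict.fromkeys(fds)))


def closures_agree(result, oracle):
    """Armstrong closures of every nonempty subset match between the
    discovered FD set (equivalences expanded) and the oracle's."""
    mine = expanded_fdset(result, oracle.universe)
    u = oracle.universe
    for size in range(1, len(u) + 1):
        for subset in combinations(u, size):
            if armstrong_closure(subset, mine) != armstrong_closure(subset, oracle):
                return False
    return True


@lru_cache(maxsize=1)
def ab_key_relation():
    """A 5-attribute relation where {A,B} is a key and the oracle finds no
    other minimal FDs (so the only minimal FDs are AB -> C, AB -> D, AB -> E).

    Built by seeded rejection against the brute-force oracle, so the
    planted situation is certified, not assumed.
    """
    from fdminer.testkit import brute_force_minimal_fds

    expected = {
        FunctionalDependency(("A", "B"), "C"),
        FunctionalDependency(("A", "B"), "D"),
        FunctionalDependency(("A", "B"), "E"),
    }
    rng = random.Random(424242)
    all_pairs = [(i, j) for i in range(6) for j in range(6)]
    for _ in range(500):
        pairs = rng.sample(all_pairs, 24)
        rows = tuple(
            (
                str(a),
                str(b),
                str(rng.randrange(3)),
                str(rng.randrange(3)),
                str(rng.randrange(3)),
            )
            for a, b in pairs
        )
        rel = Relation("abkey", ("A", "B", "C", "D", "E"), rows)
        if set(brute_force_minimal_fds(rel).fds) == expected:
            return rel
    raise RuntimeError("rejection sampling failed to produce the AB-key relation")
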