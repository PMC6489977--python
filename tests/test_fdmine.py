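import random
from itertools import combinations

import pytest

from fdminer.errors import SchemaError
from fdminer.fdmine import (
    ClosureMap,
    Counters,
    EquivalenceRegistry,
    FunctionalDependency,
    closure_of_subset,
    obtain_equivalences,
    obtain_fds,
    prune,
    run_fdmine,
)
from fdminer.lattice import CandidateLevel, attribute_set
from fdminer.relation_io import Relation
from fdminer.testkit import brute_force_minimal_fds, generate_fd_free_relation

from helpers import ab_key_relation, closures_agree, pairwise_fd_check


def _singleton_level(attrs):
    return CandidateLevel(1, tuple((a,) for a in sorted(attrs)))


def test_obtain_fds_level_one_worked_example(table):
    closures, counters = ClosureMap(), Counters()
    found = obtain_fds(table, _singleton_level(table.attributes), closures, counters)
    assert found == [
        FunctionalDependency(("A",), "D"),
        FunctionalDependency(("D",), "A"),
    ]
    assert counters.candidates_checked == 5
    assert counters.fds_found == 2
    assert closures.entries[("A",)] == {"D"}
    assert closures.entries[("B",)] == set()


def test_obtain_fds_skips_candidates_with_full_closure(table):
    # X with X union X* = U has an empty right-hand-side pool: it is
    # counted but performs no validation
    closures, counters = ClosureMap(), Counters()
    closures.entries[("A",)] = {"B", "C", "D", "E"}
    level = CandidateLevel(1, (("A",),))
    assert obtain_fds(table, level, closures, counters) == []
    assert counters.candidates_checked == 1


def test_obtain_fds_single_column_relation():
    rel = Relation("one", ("A",), (("1",), ("2",)))
    closures, counters = ClosureMap(), Counters()
    found = obtain_fds(rel, _singleton_level(rel.attributes), closures, counters)
    assert found == [] and counters.candidates_checked == 1


def test_obtain_equivalences_worked_example(table):
    closures, counters = ClosureMap(), Counters()
    level = _singleton_level(table.attributes)
    obtain_fds(table, level, closures, counters)
    registry = obtain_equivalences(level, closures, EquivalenceRegistry())
    assert registry.pairs == [(("A",), ("D",))]
    assert registry.deleted == {("A",)}  # the earlier-generated side goes


def test_obtain_equivalences_no_closures_is_noop():
    closures = ClosureMap()
    level = CandidateLevel(1, (("A",), ("B",)))
    registry = obtain_equivalences(level, closures, EquivalenceRegistry())
    assert registry.pairs == [] and registry.deleted == set()


def test_obtain_equivalences_records_pair_once():
    closures = ClosureMap()
    closures.entries[("A",)] = {"B"}
    closures.entries[("B",)] = {"A"}
    registry = obtain_equivalences(
        CandidateLevel(1, (("A",), ("B",))), closures, EquivalenceRegistry()
    )
    assert registry.pairs == [(("A",), ("B",))]


def test_prune_deletes_supersets_of_a_key():
    # {A,B} is a key of a 5-attribute schema with no other FDs: ABC, ABD
    # and ABE are contained in AB's closure and disappear from level 3
    universe = attribute_set("ABCDE")
    closures = ClosureMap()
    for pair in combinations(universe, 2):
        closures.entries[pair] = set()
    closures.entries[("A", "B")] = {"C", "D", "E"}
    level3 = CandidateLevel(3, tuple(combinations(universe, 3)))
    pruned = prune(level3, EquivalenceRegistry(), closures, universe)
    assert pruned.candidates == tuple(
        sorted(
            attribute_set(c)
            for c in ["ACD", "ACE", "ADE", "BCD", "BCE", "BDE", "CDE"]
        )
    )


def test_prune_without_state_is_identity():
    universe = attribute_set("ABCD")
    level2 = CandidateLevel(2, tuple(combinations(universe, 2)))
    pruned = prune(level2, EquivalenceRegistry(), ClosureMap(), universe)
    assert pruned.candidates == level2.candidates


def test_prune_equivalence_rule_removes_all_supersets_of_deleted_side():
    universe = attribute_set("ABCD")
    registry = EquivalenceRegistry(pairs=[(("A",), ("D",))], deleted={("A",)})
    closures = ClosureMap()
    closures.entries[("A",)] = {"D"}
    closures.entries[("D",)] = {"A"}
    level2 = CandidateLevel(2, tuple(combinations(universe, 2)))
    pruned = prune(level2, registry, closures, universe)
    assert all("A" not in c for c in pruned.candidates)
    # the deleted side's closure is still propagated to its supersets
    assert "D" in closures.entries[("A", "B")]


def test_prune_keeps_full_set_as_candidate():
    # U is only trivially a superkey; it stays (and is later counted)
    universe = attribute_set("ABC")
    level3 = CandidateLevel(3, (universe,))
    pruned = prune(level3, EquivalenceRegistry(), ClosureMap(), universe)
    assert pruned.candidates == (universe,)


def test_closure_of_subset_resolution():
    closures = ClosureMap()
    closures.entries[("A",)] = {"D"}
    closures.entries[("B",)] = set()
    assert closure_of_subset(("A",), closures) == {"D"}  # stored lookup
    assert closure_of_subset(("A", "B"), closures) == {"D"}  # union of subsets
    assert closure_of_subset(("Z",), closures) == set()  # never generated


def test_run_fdmine_worked_example(table):
    result = run_fdmine(table)
    assert FunctionalDependency(("A",), "D") in result.fds
    assert FunctionalDependency(("D",), "A") in result.fds
    assert (("A",), ("D",)) in result.equivalences
    assert result.keys == (("A", "B", "C"), ("B", "C", "D"), ("B", "C", "E"))
    assert result.fds_found == len(result.fds)
    assert result.rows == 7 and result.attribute_count == 5
    assert not result.truncated
    # levels: 5 singletons + 6 surviving pairs; level 3 is fully pruned
    assert result.candidates_checked == 11


def test_run_fdmine_is_row_order_independent(table):
    shuffled_rows = list(table.rows)
    random.Random(11).shuffle(shuffled_rows)
    shuffled = Relation(table.name, table.attributes, tuple(shuffled_rows))
    a, b = run_fdmine(table), run_fdmine(shuffled)
    assert a.fds == b.fds
    assert a.equivalences == b.equivalences
    assert a.keys == b.keys
    assert a.candidates_checked == b.candidates_checked


def test_run_fdmine_emits_only_sound_fds(table):
    result = run_fdmine(table)
    for fd in result.fds:
        assert pairwise_fd_check(table, fd.lhs, fd.rhs)


def test_run_fdmine_single_attribute_relation():
    distinct = Relation("k", ("A",), (("1",), ("2",)))
    result = run_fdmine(distinct)
    assert result.fds == () and result.keys == (("A",),)
    repeated = Relation("k", ("A",), (("1",), ("1",)))
    assert run_fdmine(repeated).fds == ()


def test_run_fdmine_counts_fifteen_candidates_on_fd_free_four_attributes():
    relation = generate_fd_free_relation(500, ("A", "B", "C", "D"), seed=5)
    assert not brute_force_minimal_fds(relation).fds
    result = run_fdmine(relation)
    assert result.candidates_checked == 15  # 4 + 6 + 4 + 1, full set included
    assert result.fds_found == 0


def test_run_fdmine_minimality_after_key_pruning():
    """With {A,B} a key and no other FDs, no non-minimal superset FD
    (such as ABCD -> E) may appear, and the search checks 5 + 10 + 7 + 2
    candidates: the corrected generation skips every superset of AB at
    level 4."""
    relation = ab_key_relation()
    result = run_fdmine(relation)
    assert set(result.fds) == {
        FunctionalDependency(("A", "B"), "C"),
        FunctionalDependency(("A", "B"), "D"),
        FunctionalDependency(("A", "B"), "E"),
    }
    assert result.equivalences == ()
    assert result.keys == (("A", "B"),)
    assert result.candidates_checked == 24
    assert closures_agree(result, brute_force_minimal_fds(relation))


def test_run_fdmine_time_limit_truncates(table):
    result = run_fdmine(table, time_limit_seconds=1e-9)
    assert result.truncated
    assert result.candidates_checked == 0


def test_run_fdmine_rejects_degenerate_inputs(table):
    with pytest.raises(SchemaError):
        run_fdmine(Relation("none", (), ()))
    with pytest.raises(ValueError):
        run_fdmine(table, time_limit_seconds=0)


def test_run_fdmine_terminates_within_attribute_count_levels(table):
    result = run_fdmine(table)
    assert result.candidates_checked <= 2 ** len(table.attributes) - 1
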