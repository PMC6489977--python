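"""Plant dependency structure in a synthetic relation and recover it.

Generates a 300-row table where column B is a function of A and column D
mirrors A through a bijection, then checks that the discovered FD set
implies exactly that structure.
"""

from fdminer import armstrong_closure, run_fdmine
from fdminer.fdmine import FunctionalDependency
from fdminer.keyinfer import FDSet
from fdminer.testkit import SyntheticSpec, generate_relation

spec = SyntheticSpec(
    n_rows=300,
    attributes=("A", "B", "C", "D"),
    planted_fds=(FunctionalDependency(("A",), "B"),),
    planted_equivalences=(("A", "D"),),
    seed=42,
)
relation = generate_relation(spec)
print(f"generated {relation.n_rows} rows; planted {{A}} -> {{B}} and A <-> D")

result = run_fdmine(relation)
print("\ndiscovered FDs:")
for fd in result.fds:
    print(f"  {fd}")
print("equivalences:", ["{%s} <-> {%s}" % (", ".join(x), ", ".join(y))
                        for x, y in result.equivalences])

# the planted structure must be implied by what was discovered
fds = list(result.fds)
for x, y in result.equivalences:
    fds += [FunctionalDependency(x, a) for a in set(y) - set(x)]
    fds += [FunctionalDependency(y, a) for a in set(x) - set(y)]
implied = FDSet(universe=tuple(sorted(relation.attributes)), fds=tuple(fds))
print("\nclosure of {A}:", armstrong_closure(("A",), implied),
      " <- contains B and D, so the planted structure was recovered")
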