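"""Armstrong closures, minimum coverage and candidate keys from an FD set.

Works directly on a hand-written FD set — no table needed — the way one
reasons about a schema on paper.
"""

from fdminer import armstrong_closure, candidate_keys, minimum_coverage
from fdminer.fdmine import FunctionalDependency as FD
from fdminer.keyinfer import FDSet

# a toy patient-visit schema: visit id determines everything; patient id
# determines the demographics; {A -> BCDE-ish structure with a redundancy}
f = FDSet(
    universe=("clinic", "patient", "visit", "date"),
    fds=(
        FD(("visit",), "patient"),
        FD(("visit",), "date"),
        FD(("patient",), "clinic"),
        FD(("visit",), "clinic"),  # redundant: implied through patient
    ),
)

print("closure of {visit}: ", armstrong_closure(("visit",), f))
print("closure of {patient}:", armstrong_closure(("patient",), f))

cover = minimum_coverage(f)
print("\nminimum coverage (redundant FDs dropped, left sides reduced):")
for fd in cover.fds:
    print(f"  {fd}")

print("\ncandidate keys:", candidate_keys(f),
      " <- visit alone reaches every attribute, nothing smaller does")
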